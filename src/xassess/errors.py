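"""Exception types shared across the package."""


class XassessError(Exception):
    """Base class for package errors."""


class FormatError(XassessError):
    """A file does not conform to its expected format."""


class ValidationError(XassessError):
    """Inputs are well-formed but semantically inconsistent."""


class MetricNotApplicableError(XassessError):
    """A metric cannot be computed for the given output type or labels.

    Raised e.g. when an embedding-based metric is asked to score a k-NN-graph
    integration output, or when only a single species/batch is present.
    Callers that assemble metric tables catch this and record the entry as
    not-applicable rather than failing the run.
    """
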