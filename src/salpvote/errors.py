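"""Exception types shared across the package."""


class DataFormatError(ValueError):
    """The input table violates the expected layout (labels, ids, numeric cells)."""


class ConfigError(ValueError):
    """A configuration object violates its invariants."""


class StratificationError(ValueError):
    """A class is too small to stratify (splitting or cross-validation)."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""
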