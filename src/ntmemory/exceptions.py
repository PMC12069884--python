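"""Exception types shared across the package."""


class ConfigError(ValueError):
    """Invalid simulation or threshold configuration."""


class FormatError(ValueError):
    """A file on disk violates the expected format (names the offending file)."""


class DesignError(ValueError):
    """A statistical design is degenerate (e.g. condition fully confounded with batch)."""


class HomeologAmbiguityError(ValueError):
    """Three or more rows collapse to a single base gene symbol."""
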