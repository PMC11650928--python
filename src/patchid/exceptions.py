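"""Exception hierarchy for patchid."""


class PatchidError(Exception):
    """Base class for all patchid errors."""


class FormatError(PatchidError):
    """A file or record violates its declared on-disk format."""


class ConfigError(PatchidError):
    """Invalid configuration or argument combination."""


class RenderError(PatchidError):
    """Synthetic rendering cannot satisfy the requested geometry."""


class NotFittedError(PatchidError):
    """A model was used before it was fitted."""
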