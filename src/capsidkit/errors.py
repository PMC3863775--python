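"""Exception hierarchy shared across the toolkit."""


class CapsidkitError(Exception):
    """Base class for all toolkit errors."""


class ParseError(CapsidkitError):
    """A structure or volume file could not be parsed."""


class FormatError(CapsidkitError):
    """Unknown or unsupported file format."""


class SelectionError(CapsidkitError):
    """A residue/atom selection could not be resolved."""


class EmptySelectionError(SelectionError):
    """A selection resolved to zero atoms (explicit, never silent)."""


class ValidationError(CapsidkitError):
    """Invalid domain object (partition, config, ring, ...)."""


class GeometryError(CapsidkitError):
    """Degenerate or unsatisfiable geometry."""
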