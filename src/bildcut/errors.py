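"""Exception hierarchy shared across the package."""


class BildcutError(Exception):
    """Base class for all package-specific errors."""


class BlastParseError(BildcutError):
    """A BLAST tabular line could not be parsed (field count, numeric fields)."""


class ValidationError(BildcutError):
    """Parsed data violates a structural invariant."""


class ConsistencyError(BildcutError):
    """Two inputs that must describe the same object disagree."""


class TaxonomyError(BildcutError):
    """Taxonomy table violates the six-rank lineage contract."""


class LookupError_(BildcutError):
    """An identifier required downstream is missing from a mapping."""
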