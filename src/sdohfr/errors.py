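"""Exception hierarchy shared across the toolkit."""


class SdohError(Exception):
    """Base class for all toolkit errors."""


class SchemaError(SdohError):
    """A label, relation type, attribute value or triple is not in the scheme."""


class IntegrityError(SdohError):
    """Standoff data does not line up with the source text (offsets, surfaces, ids)."""


class AlignmentError(SdohError):
    """Two corpora or annotator sets do not share the same document ids."""


class ConfigError(SdohError):
    """A user-supplied configuration (lexicon, map, generator settings) is invalid."""
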