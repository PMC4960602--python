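"""Exception hierarchy for the prioritization pipeline."""


class VarprioError(Exception):
    """Base class for all package errors."""


class VcfParseError(VarprioError):
    """A VCF could not be parsed, or its samples are inconsistent with the pedigree."""


class PedigreeError(VarprioError):
    """PED / sequenced-sample input is malformed or inconsistent."""


class AnnotationError(VarprioError):
    """Annotation table is malformed (bad range, duplicate key, missing column)."""


class GeneListError(VarprioError):
    """Gene panel / blacklist file is empty or unreadable."""


class ConfigError(VarprioError):
    """A filter or simulation configuration violates its invariants."""


class JoinError(VarprioError):
    """Variant records and annotation rows could not be joined."""
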