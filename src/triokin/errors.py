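"""Exception types shared across the package."""


class TriokinError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TriokinError):
    """Invalid user configuration (roles, populations, modes, config files)."""


class VcfParseError(TriokinError):
    """A VCF record or file could not be parsed."""


class PhaseUndeterminedError(TriokinError):
    """Compound-heterozygote phasing requested without both parents."""


class CapacityError(TriokinError):
    """The synthetic generator was asked to inject more variants than fit."""


class PedigreeError(TriokinError):
    """Structural problem in a pedigree specification."""
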