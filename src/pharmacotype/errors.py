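"""Exception types raised across the pipeline."""


class PharmacotypeError(Exception):
    """Base class for all pipeline errors."""


class PlateFormatError(PharmacotypeError):
    """Malformed or inconsistent plate-reader input."""


class PanelError(PharmacotypeError):
    """Invalid dose panel or measurement outside the declared panel."""


class RegimenError(PharmacotypeError):
    """Invalid regimen definition (empty or unscreened components)."""


class DegenerateControlError(PharmacotypeError):
    """Control wells carry no usable signal (net control signal <= 0)."""


class ClassificationError(PharmacotypeError):
    """Natural-breaks clustering cannot be performed on the given data."""


class NotSeparableError(PharmacotypeError):
    """Hard-margin SVM training data is not linearly separable."""


class CohortError(PharmacotypeError):
    """Cohort table invalid or a requested stratum is empty."""
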