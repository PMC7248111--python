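"""Exception hierarchy.

Three branches matter to callers (and map onto CLI exit codes):
``InputError`` for malformed user input, ``ModelDomainError`` for physically
valid input outside the model's validity domain, ``EstimationError`` for
numerical procedures that fail to converge or lack data.
"""


class BloodPoolError(Exception):
    """Base class for all errors raised by this package."""


class InputError(BloodPoolError, ValueError):
    """Malformed or inconsistent user input (files, arrays, parameters)."""


class ModelDomainError(BloodPoolError, ValueError):
    """Input is outside the validity domain of the physical model."""


class ApproximationRangeError(ModelDomainError):
    """The gravity-flattened puddle approximation does not apply.

    Raised when the contact-angle relation would require arccos of an
    argument below -1, i.e. the pool is too heaped for the pancake limit.
    Never silently clamped.
    """


class StillWetError(ModelDomainError):
    """The pool shows no drying front yet (wet area equals total area)."""


class FullyDriedError(ModelDomainError):
    """The pool is fully desiccated; the drying-front method no longer applies."""


class CalibrationDomainError(ModelDomainError):
    """Ambient conditions differ from those under which the diffusion plateau
    was calibrated (~23 degC, ~20% RH); pass force=True to override."""


class EstimationError(BloodPoolError, RuntimeError):
    """A fit or statistical estimate could not be computed."""


class NoPoolFoundError(InputError):
    """Segmentation found no blood-coloured region above the size threshold."""
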