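"""Exception types raised across the package."""


class DrugScreenError(Exception):
    """Base class for all package errors."""


class PlateConfigurationError(DrugScreenError):
    """A plate is missing the control wells required for normalization."""


class DegeneratePlateError(DrugScreenError):
    """Background and untreated well means coincide; viability is undefined."""


class SchemaError(DrugScreenError):
    """An input table does not match the documented column schema."""


class DesignError(DrugScreenError):
    """An analysis was requested on data whose design does not support it."""
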