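"""Neural-mass models with a uniform derivative contract."""

from .base import ModelState, NeuralMassModel, as_region_vector
from .bei import (BEIModel, BEIParams, bei_derivatives, gain_function,
                  regional_gain)
from .fre import (FREModel, FREParams, fre_derivatives,
                  single_population_fixed_point)
from .adex import (AdExFirstOrderModel, AdExSecondOrderModel, AdExParams,
                   TransferCoeffs, adex_first_order_derivatives,
                   adex_second_order_derivatives, membrane_statistics,
                   transfer_function)

MODEL_REGISTRY = {
    "bei": (BEIModel, BEIParams),
    "fre": (FREModel, FREParams),
    "adex1": (AdExFirstOrderModel, AdExParams),
    "adex2": (AdExSecondOrderModel, AdExParams),
}


def build_model(name: str, n_regions: int, params=None):
    """Instantiate a registered model by name."""
    if name not in MODEL_REGISTRY:
        raise KeyError(f"unknown model {name!r}; "
                       f"choose from {sorted(MODEL_REGISTRY)}")
    cls, params_cls = MODEL_REGISTRY[name]
    if params is None:
        params = params_cls() if name != "adex2" else params_cls(order=2)
    elif isinstance(params, dict):
        params = params_cls(**params)
    return cls(n_regions, params)


__all__ = [
    "ModelState", "NeuralMassModel", "as_region_vector",
    "BEIModel", "BEIParams", "bei_derivatives", "gain_function",
    "regional_gain",
    "FREModel", "FREParams", "fre_derivatives",
    "single_population_fixed_point",
    "AdExFirstOrderModel", "AdExSecondOrderModel", "AdExParams",
    "TransferCoeffs", "adex_first_order_derivatives",
    "adex_second_order_derivatives", "membrane_statistics",
    "transfer_function",
    "MODEL_REGISTRY", "build_model",
]
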