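"""Apply the four cmc models to descriptor rows or structures.

Each model is a linear relation ``logcmc = intercept + sum(coef * chi)``
on the molar log10 scale; the millimolar cmc follows as
``10 ** (logcmc + 3)``.  Two coefficient sources are supported:
``printed`` (the published coefficients, for reproduction) and ``refit``
(re-derived from the packaged training matrix by the selection
procedure).

Model summary (printed source):

=====  ==================  ============================================
model  predictors          equation
=====  ==================  ============================================
1      chi2                logcmc = -0.17261 - 0.184411 * chi2
2      chi1, chi3cv        logcmc =  0.18447 - 0.14866 * chi1 - 0.19248 * chi3cv
3      chi0v               logcmc =  0.44266 - 0.12317 * chi0v
4      chi1v               logcmc =  0.56045 - 0.20443 * chi1v
=====  ==================  ============================================

Model 4 trades a little fit quality for the index that best tracks how
branching and heteroatoms shift the cmc of these surfactants.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Literal

from .chi_indices import descriptor_row
from .dataset import DescriptorRow, load_training
from .molgraph import MolecularGraph, parse_smiles
from .regression_stats import RegressionModel

__all__ = ["PredictionResult", "printed_models", "refit_models", "predict", "predict_from_structure"]

Source = Literal["printed", "refit"]

#: published coefficients and (for reference) the published fit statistics
_PRINTED: dict[int, dict] = {
    1: {
        "predictors": ("chi2",),
        "intercept": -0.17261,
        "coefficients": (-0.184411,),
        "r": 0.982,
        "F": 563.629,
        "s": 0.095,
        "r2": 0.964,
    },
    2: {
        "predictors": ("chi1", "chi3cv"),
        "intercept": 0.18447,
        "coefficients": (-0.14866, -0.19248),
        "r": 0.983,
        "F": 585.435,
        "s": 0.093,
        "r2": 0.966,
    },
    3: {
        "predictors": ("chi0v",),
        "intercept": 0.44266,
        "coefficients": (-0.12317,),
        "r": 0.975,
        "F": 403.639,
        "s": 0.111,
        "r2": 0.951,
    },
    4: {
        "predictors": ("chi1v",),
        "intercept": 0.56045,
        "coefficients": (-0.20443,),
        "r": 0.957,
        "F": 231.36,
        "s": 0.144,
    },
}


@dataclass(frozen=True)
class PredictionResult:
    """A single cmc prediction."""

    name: str
    model_id: int
    source: Source
    logcmc_pred: float
    cmc_mM: float
    residual: float | None = None  # experimental - predicted, when known
    descriptor_provenance: str = "printed"


def printed_models() -> dict[int, RegressionModel]:
    """The four models with coefficients exactly as published.

    The statistics fields carry the published figure-caption values for
    reference; fitted values and residuals are left empty.
    """
    out = {}
    for mid, spec in _PRINTED.items():
        out[mid] = RegressionModel(
            predictors=spec["predictors"],
            intercept=spec["intercept"],
            coefficients=spec["coefficients"],
            n=23,
            r2=spec.get("r2", spec["r"] ** 2),
            r=spec["r"],
            F=spec["F"],
            s=spec["s"],
            source="printed",
        )
    return out


@lru_cache(maxsize=1)
def refit_models() -> dict[int, RegressionModel]:
    """Models 1-4 re-derived from the packaged training matrix."""
    from .model_selection import run_selection

    return dict(run_selection(load_training()).final_models)


def _get_model(model_id: int, source: Source) -> RegressionModel:
    models = printed_models() if source == "printed" else refit_models()
    if model_id not in models:
        raise KeyError(f"unknown model id {model_id}; available: {sorted(models)}")
    return models[model_id]


def predict(row: DescriptorRow, model_id: int, source: Source = "printed") -> PredictionResult:
    """Predict cmc for a descriptor row under one of the four models."""
    model = _get_model(model_id, source)
    x = model.design_vector(row.indices)
    logcmc = float(model.intercept + x @ model.coefficients)
    return PredictionResult(
        name=row.name,
        model_id=model_id,
        source=source,
        logcmc_pred=logcmc,
        cmc_mM=10.0 ** (logcmc + 3.0),
        residual=None if row.logcmc is None else row.logcmc - logcmc,
        descriptor_provenance=row.provenance,
    )


def predict_from_structure(
    structure: str | MolecularGraph,
    model_id: int,
    source: Source = "printed",
    logcmc_exp: float | None = None,
    name: str = "",
) -> PredictionResult:
    """End-to-end prediction: SMILES (or graph) -> indices -> cmc."""
    if isinstance(structure, MolecularGraph):
        graph = structure
    else:
        graph = parse_smiles(structure, name=name)
    row = DescriptorRow(
        name=name or graph.name or "structure",
        indices=descriptor_row(graph),
        logcmc=logcmc_exp,
        provenance="derived",
    )
    return predict(row, model_id, source)
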