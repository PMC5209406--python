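"""Stepwise descriptor selection for the cmc models.

The procedure mirrors how single- and two-descriptor QSPR models are built
from a small training matrix:

* **Step 1** — fit logcmc on each of the ten indices separately and rank
  by fit quality (highest r2/r/F, lowest s; all equivalent at fixed n).
* **Collinearity screen** — classify every descriptor pair by the
  magnitude of its Pearson correlation: ``high`` (r >= 0.97),
  ``appreciable`` (0.90 <= r < 0.97), ``weak`` (0.50 <= r < 0.90),
  ``none`` (r < 0.50).  Well-performing indices that are highly
  correlated with a better-ranked base and judged structurally redundant
  are dropped.
* **Step 2** — to each retained base, add every remaining index
  separately; an extension is considered only when the two-descriptor r
  (at three printed decimals) beats both the base and the best
  single-index model.
* **Step 3** — attempt a third descriptor on any extended model; stop
  when the gain falls below the acceptance threshold.

Several choices in the reference selection path are expert judgments, not
statistics: dropping chi0 as redundant with chi2, rejecting the marginal
step-2 gain on the chi2 base, preferring the valence cluster index chi3cv
over chi3c when tied (it carries heteroatom information), and designating
the chi1v single-index model as a fourth model on interpretability
grounds.  These are encoded as explicit entries of the default
:class:`SelectionConfig` and every application of one is written to the
decision log, so the automated rules and the overrides stay separable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .dataset import INDEX_COLUMNS, QsprDataset
from .regression_stats import CollinearityError, RegressionModel, ols_fit, pearson_matrix

__all__ = [
    "SelectionConfig",
    "SelectionReport",
    "step1_screen",
    "classify_collinearity",
    "step_extend",
    "run_selection",
    "DEFAULT_CONFIG",
]

#: pretty labels for reports
INDEX_LABELS = {
    "chi0": "0chi", "chi1": "1chi", "chi2": "2chi", "chi3c": "3chi_c",
    "chi4pc": "4chi_pc", "chi0v": "0chi_v", "chi1v": "1chi_v",
    "chi2v": "2chi_v", "chi3cv": "3chi_c_v", "chi4pcv": "4chi_pc_v",
}


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds and expert overrides steering :func:`run_selection`."""

    #: band edges for correlation classes (high, appreciable, weak)
    high_corr: float = 0.97
    appreciable_corr: float = 0.90
    weak_corr: float = 0.50
    #: step-1 r needed for an index to become a model base
    base_r_threshold: float = 0.97
    #: minimum gain in r (at `decimals` places) to accept an extension
    min_delta_r: float = 0.001
    #: printed precision at which r values are compared
    decimals: int = 3
    #: expert override: (drop, keep) pairs of redundant high-correlation bases
    drop_redundant: tuple[tuple[str, str], ...] = (("chi0", "chi2"),)
    #: expert override: predictor sets whose further extension is judged
    #: insignificant even when a candidate clears ``min_delta_r``
    stop_stepping: tuple[tuple[str, ...], ...] = (("chi2",), ("chi1", "chi3cv"))
    #: expert override: preferred index when step-2 candidates tie
    extension_preference: dict[str, str] = field(
        default_factory=lambda: {"chi1": "chi3cv"}
    )
    #: expert override: additional single-index models kept for interpretability
    expert_models: tuple[tuple[str, ...], ...] = (("chi1v",),)

    def __post_init__(self) -> None:
        if not (0 <= self.weak_corr <= self.appreciable_corr <= self.high_corr <= 1):
            raise ValueError("correlation bands must be ordered within [0, 1]")
        if self.min_delta_r < 0 or not (0 <= self.base_r_threshold <= 1):
            raise ValueError("invalid selection thresholds")
        for col in [c for pair in self.drop_redundant for c in pair] + [
            c for preds in self.stop_stepping for c in preds
        ]:
            if col not in INDEX_COLUMNS:
                raise ValueError(f"unknown index column {col!r} in config")


DEFAULT_CONFIG = SelectionConfig()


@dataclass(frozen=True)
class SelectionReport:
    step1: pd.DataFrame                      # one row per index: r, F, s, rank
    corr_matrix: pd.DataFrame
    corr_classes: dict[tuple[str, str], str]
    n_high_pairs: int
    step_tables: dict[int, dict[str, float | None]]  # model id -> added index -> r
    decisions: tuple[str, ...]
    final_models: dict[int, RegressionModel]


def step1_screen(dataset: QsprDataset) -> pd.DataFrame:
    """One single-index fit per descriptor, ranked by fit quality.

    Ties in r2 are broken by s, then by column order; the ranking is
    invariant under row permutations of the dataset.
    """
    records = []
    for pos, col in enumerate(INDEX_COLUMNS):
        m = ols_fit(dataset, [col])
        records.append({"index": col, "r": m.r, "F": m.F, "s": m.s, "r2": m.r2, "_pos": pos})
    df = pd.DataFrame(records).sort_values(
        by=["r2", "s", "_pos"], ascending=[False, True, True], kind="stable"
    )
    df["rank"] = range(1, len(df) + 1)
    return df.drop(columns=["_pos"]).set_index("index")


def classify_collinearity(
    corr: pd.DataFrame, config: SelectionConfig = DEFAULT_CONFIG
) -> dict[tuple[str, str], str]:
    """Label every descriptor pair with its correlation class.

    Correlations are rounded to the configured printed precision before
    banding, matching how the reference tables are read.
    """
    labels: dict[tuple[str, str], str] = {}
    cols = list(corr.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            r = round(abs(float(corr.loc[a, b])), config.decimals)
            if r >= config.high_corr:
                label = "high"
            elif r >= config.appreciable_corr:
                label = "appreciable"
            elif r >= config.weak_corr:
                label = "weak"
            else:
                label = "none"
            labels[(a, b)] = label
    return labels


def step_extend(
    base: RegressionModel, dataset: QsprDataset, decimals: int = 3
) -> dict[str, float | None]:
    """Fit base + one extra index for every remaining index.

    Returns r (rounded to ``decimals``) per candidate; the base's own
    predictors map to ``None`` (the dash of the printed tables), as does
    any candidate whose design matrix is singular.
    """
    if len(base.predictors) >= 3:
        raise ValueError("step_extend supports bases with fewer than 3 predictors")
    out: dict[str, float | None] = {}
    for col in INDEX_COLUMNS:
        if col in base.predictors:
            out[col] = None
            continue
        try:
            m = ols_fit(dataset, list(base.predictors) + [col])
        except CollinearityError:
            out[col] = None
            continue
        out[col] = round(m.r, decimals)
    return out


def run_selection(
    dataset: QsprDataset, config: SelectionConfig = DEFAULT_CONFIG
) -> SelectionReport:
    """Run the full stepwise procedure and emit the final model set."""
    decisions: list[str] = []
    rnd = lambda x: round(x, config.decimals)

    # ---- step 1 ----------------------------------------------------------
    step1 = step1_screen(dataset)
    best_single_r = rnd(float(step1["r"].max()))
    best_index = step1.index[0]
    decisions.append(
        f"step1: best single index is {best_index} (r={best_single_r:.{config.decimals}f})"
    )

    # ---- collinearity screen --------------------------------------------
    corr = pearson_matrix(dataset)
    classes = classify_collinearity(corr, config)
    n_high = sum(1 for v in classes.values() if v == "high")
    decisions.append(f"collinearity: {n_high} highly correlated pairs (r >= {config.high_corr})")

    # ---- base selection --------------------------------------------------
    bases = [c for c in step1.index if rnd(float(step1.loc[c, "r"])) >= config.base_r_threshold]
    for drop, keep in config.drop_redundant:
        if drop in bases and keep in bases:
            pair = (drop, keep) if (drop, keep) in classes else (keep, drop)
            if classes.get(pair) == "high":
                bases.remove(drop)
                decisions.append(
                    f"override: drop {drop} as structurally redundant with {keep} "
                    f"(r={corr.loc[drop, keep]:.{config.decimals}f})"
                )
    decisions.append(f"bases retained (step-1 order): {', '.join(bases)}")

    # ---- steps 2 and 3 ---------------------------------------------------
    step_tables: dict[int, dict[str, float | None]] = {}
    final_models: dict[int, RegressionModel] = {}
    for model_id, base_col in enumerate(bases, start=1):
        model = ols_fit(dataset, [base_col])
        table = step_extend(model, dataset, config.decimals)
        step_tables[model_id] = table
        while len(model.predictors) < 3:
            if model.predictors in config.stop_stepping:
                decisions.append(
                    f"override: model {model_id} ({'+'.join(model.predictors)}) kept as is; "
                    "further gains judged insignificant"
                )
                break
            current = step_extend(model, dataset, config.decimals)
            floor = max(rnd(model.r) + config.min_delta_r, best_single_r + config.min_delta_r)
            candidates = [c for c, r in current.items() if r is not None and r >= floor]
            if not candidates:
                decisions.append(
                    f"model {model_id}: no extension of {'+'.join(model.predictors)} "
                    f"reaches r >= {floor:.{config.decimals}f}; stepping ends"
                )
                break
            top_r = max(current[c] for c in candidates)
            top = [c for c in candidates if current[c] == top_r]
            preferred = config.extension_preference.get(base_col)
            if len(top) > 1 and preferred in top:
                choice = preferred
                decisions.append(
                    f"override: model {model_id} tie at r={top_r:.{config.decimals}f} among "
                    f"{', '.join(top)}; {choice} preferred (richer structural information)"
                )
            else:
                choice = top[0]
                decisions.append(
                    f"model {model_id}: extend {'+'.join(model.predictors)} with {choice} "
                    f"(r={top_r:.{config.decimals}f})"
                )
            model = ols_fit(dataset, list(model.predictors) + [choice])
        final_models[model_id] = model

    for extra in config.expert_models:
        model_id = len(final_models) + 1
        final_models[model_id] = ols_fit(dataset, list(extra))
        decisions.append(
            f"override: model {model_id} ({'+'.join(extra)}) added on interpretability grounds"
        )

    return SelectionReport(
        step1=step1,
        corr_matrix=corr,
        corr_classes=classes,
        n_high_pairs=n_high,
        step_tables=step_tables,
        decisions=tuple(decisions),
        final_models=final_models,
    )
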