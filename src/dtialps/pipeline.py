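"""Batch orchestration: per-subject ALPS computation and the association screen."""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alps import ROIConfig, alps_from_volumes
from .stats import (
    NormalityResult,
    benjamini_hochberg,
    group_compare,
    lilliefors_normality,
    pearson_test,
)
from .tensor import TensorVolume

__all__ = [
    "SubjectVolumes",
    "BatteryItem",
    "AssociationReport",
    "run_alps_batch",
    "run_association_screen",
    "published_battery",
]

log = logging.getLogger(__name__)


@dataclass
class SubjectVolumes:
    """One subject's inputs for the ALPS stage, already in atlas space."""

    subject_id: str
    tensor: TensorVolume
    labels: np.ndarray


@dataclass(frozen=True)
class BatteryItem:
    """One screened variable: continuous → Pearson test against the
    outcome; binary → group comparison of the outcome.  ``tails`` and
    ``direction`` configure the Pearson tail (e.g. the astrocytic-injury
    hypothesis pre-declares a one-tailed negative test for blood GFAP)."""

    name: str
    kind: str = "continuous"
    tails: str = "two"
    direction: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"battery item {self.name!r}: bad kind {self.kind!r}")
        if self.tails == "one" and self.direction not in ("positive", "negative"):
            raise ValueError(f"battery item {self.name!r}: one-tailed needs direction")


@dataclass
class AssociationReport:
    """Correlation and group-comparison batteries with joint FDR control."""

    continuous: pd.DataFrame
    binary: pd.DataFrame
    normality: NormalityResult | None
    q: float
    outcome: str = "alps"

    def rejected_variables(self) -> list[str]:
        out = []
        for df in (self.continuous, self.binary):
            if len(df):
                out.extend(df.loc[df["significant_fdr"], "variable"].tolist())
        return out

    def save(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.continuous.to_csv(d / "continuous_battery.tsv", sep="\t", index=False, float_format="%.6g")
        self.binary.to_csv(d / "binary_battery.tsv", sep="\t", index=False, float_format="%.6g")


def run_alps_batch(
    subjects: Iterable[SubjectVolumes], cfg: ROIConfig
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Compute the ALPS index for every subject, collecting failures.

    Returns the per-subject result table (subject_id, the four ROI means,
    voxel counts, index) and a list of (subject_id, error message) for
    subjects whose volumes could not be processed; a failure never aborts
    the batch.  Raises RuntimeError if no subject succeeds.
    """
    rows, failures = [], []
    for s in subjects:
        try:
            res = alps_from_volumes(s.tensor, s.labels, cfg)
            rows.append({"subject_id": s.subject_id, **res.as_dict()})
        except Exception as exc:  # recorded, not fatal
            failures.append((s.subject_id, str(exc)))
            log.warning("subject %s failed: %s", s.subject_id, exc)
    if not rows:
        raise RuntimeError(
            f"no subject produced an ALPS index ({len(failures)} failure(s): "
            + "; ".join(f"{sid}: {msg}" for sid, msg in failures[:5])
            + ")"
        )
    table = pd.DataFrame(rows)
    log.info(
        "ALPS batch: n=%d, mean=%.4f, SD=%.4f (%d failure(s))",
        len(table),
        table["alps_index"].mean(),
        table["alps_index"].std(ddof=1) if len(table) > 1 else float("nan"),
        len(failures),
    )
    return table, failures


def run_association_screen(
    table: pd.DataFrame,
    battery: Sequence[BatteryItem],
    outcome: str = "alps",
    q: float = 0.05,
    check_normality: bool = True,
    normality_sims: int = 2000,
    seed: int | None = 0,
) -> AssociationReport:
    """Screen every battery variable against the outcome with joint FDR.

    Continuous variables get a Pearson test (tails per item), binary ones a
    pooled t-test with Cohen's d; Benjamini–Hochberg runs once across the
    whole declared family.  Normality of the outcome is checked first
    (Lilliefors Monte-Carlo) and logged.  Unknown battery variables raise.
    """
    if outcome not in table.columns:
        raise ValueError(f"outcome column {outcome!r} not in table")
    missing = [b.name for b in battery if b.name not in table.columns]
    if missing:
        raise ValueError(f"battery variable(s) not in table: {missing}")

    normality = None
    if check_normality and len(table) >= 5:
        normality = lilliefors_normality(
            table[outcome].to_numpy(dtype=float), n_sim=normality_sims, seed=seed
        )
        log.info(
            "%s normality: D=%.3f, p=%.3f (n=%d)",
            outcome, normality.statistic, normality.p_value, normality.n,
        )

    y = table[outcome].to_numpy(dtype=float)
    cont_rows, bin_rows, pvals = [], [], []
    for item in battery:
        x = pd.to_numeric(table[item.name], errors="coerce").to_numpy(dtype=float)
        if item.kind == "continuous":
            res = pearson_test(
                x, y, tails=item.tails, direction=item.direction,
                names=(item.name, outcome),
            )
            cont_rows.append(
                {
                    "variable": item.name,
                    "n": res.n,
                    "r": res.r,
                    "t": res.t_stat,
                    "tails": res.tails,
                    "p": res.p_value,
                }
            )
            pvals.append(res.p_value)
        else:
            res = group_compare(y, x, variable=item.name)
            bin_rows.append(
                {
                    "variable": item.name,
                    "n_present": res.n1,
                    "n_absent": res.n0,
                    "mean_present": res.mean1,
                    "mean_absent": res.mean0,
                    "smd": res.smd,
                    "t": res.t_stat,
                    "p": res.p_value,
                }
            )
            pvals.append(res.p_value)

    fdr = benjamini_hochberg(pvals, q=q) if pvals else None
    cont = pd.DataFrame(cont_rows, columns=["variable", "n", "r", "t", "tails", "p"])
    bin_ = pd.DataFrame(
        bin_rows,
        columns=["variable", "n_present", "n_absent", "mean_present", "mean_absent", "smd", "t", "p"],
    )
    if fdr is not None:
        n_cont = len(cont_rows)
        adj = fdr.p_adjusted
        rej = fdr.rejected
        # battery order is continuous/binary interleaved as declared; re-split
        cont_idx, bin_idx, ci, bi = [], [], 0, 0
        for k, item in enumerate(battery):
            (cont_idx if item.kind == "continuous" else bin_idx).append(k)
        cont["p_fdr"] = adj[cont_idx]
        cont["significant_fdr"] = rej[cont_idx]
        bin_["p_fdr"] = adj[bin_idx]
        bin_["significant_fdr"] = rej[bin_idx]
    else:
        for df in (cont, bin_):
            df["p_fdr"] = pd.Series(dtype=float)
            df["significant_fdr"] = pd.Series(dtype=bool)
    return AssociationReport(continuous=cont, binary=bin_, normality=normality, q=q, outcome=outcome)


def published_battery() -> list[BatteryItem]:
    """The battery of the published screen over the synthetic cohort:
    every effect-set variable against the ALPS index, with blood GFAP
    pre-declared one-tailed negative (astrocytic-injury hypothesis)."""
    from .cohort import PUBLISHED_CORRELATIONS, PUBLISHED_GROUP_EFFECTS

    items = []
    for name in PUBLISHED_CORRELATIONS:
        if name == "gfap":
            items.append(BatteryItem(name, "continuous", tails="one", direction="negative"))
        else:
            items.append(BatteryItem(name, "continuous"))
    for name in PUBLISHED_GROUP_EFFECTS:
        items.append(BatteryItem(name, "binary"))
    return items
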