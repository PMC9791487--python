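"""Dissimilarity and repeated-measures statistics on read-out responses.

The network's response to each of the 30 grounding patterns is a vector of
firing-rate estimates per area.  A 30 × 30 representational dissimilarity
matrix (RDM) of Euclidean distances is computed per area; averaging its
entries over same-concept pairs gives the within-category dissimilarity
Dissim_W (30 pairs for a 10-concept design), over different-concept pairs
the between-category dissimilarity Dissim_B (405 pairs), and the
difference DissimDiff = Dissim_B − Dissim_W quantifies categorical
separation ("global discrimination value").  Label effects are expressed
per subject as the percentage change from the no-label to the label
condition; repeated-measures ANOVAs (two or three two-level within-subject
factors) and Bonferroni-corrected paired t-tests provide the statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import pdist, squareform

from .netcore import AREA_NAMES, EXTRASYLVIAN_CENTRAL, EXTRASYLVIAN_PRIMARY
from .protocol import ExperimentResults, ResponseMatrix

__all__ = [
    "RDM",
    "DissimSummary",
    "compute_rdm",
    "dissim_summary",
    "summarize_experiment",
    "label_effect",
    "aggregate_label_effect",
    "rm_anova",
    "posthoc_paired_tests",
    "centrality_rollup",
    "dissim_diff_permutation_null",
    "plot_rdm",
    "plot_label_effect",
]

log = logging.getLogger(__name__)

MEASURES = ("dissim_w", "dissim_b", "dissim_diff")


@dataclass
class RDM:
    """Symmetric matrix of pairwise Euclidean response distances."""

    matrix: np.ndarray
    area: str
    meta: dict

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class DissimSummary:
    dissim_w: float
    dissim_b: float

    @property
    def dissim_diff(self) -> float:
        return self.dissim_b - self.dissim_w


def compute_rdm(responses: ResponseMatrix, area: str = "all") -> RDM:
    """Pairwise Euclidean distances between per-area response vectors.

    ``area`` may be one of the 12 area names (625-dimensional vectors) or
    ``"all"`` (the 7500-dimensional concatenation over areas).
    """
    if area == "all":
        vecs = responses.all_areas()
    elif area in AREA_NAMES:
        vecs = responses.area(area)
    else:
        raise ValueError(f"unknown area {area!r}")
    mat = squareform(pdist(vecs, metric="euclidean"))
    return RDM(
        matrix=mat, area=area,
        meta={
            "semantic_type": responses.semantic_type,
            "label": responses.label,
            "subject_seed": responses.subject_seed,
        },
    )


def _pair_masks(concept_map: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    concept_map = np.asarray(concept_map)
    n = concept_map.size
    iu = np.triu_indices(n, k=1)
    same = concept_map[iu[0]] == concept_map[iu[1]]
    return iu, same


def dissim_summary(rdm: RDM, concept_map: np.ndarray) -> DissimSummary:
    """Mean within-concept and between-concept dissimilarity.

    ``concept_map`` assigns each RDM row to a concept; unordered pairs of
    distinct rows are averaged (the zero diagonal is excluded).
    """
    concept_map = np.asarray(concept_map)
    if concept_map.size != rdm.n:
        raise ValueError(
            f"concept_map length {concept_map.size} does not match RDM size {rdm.n}"
        )
    iu, same = _pair_masks(concept_map)
    vals = rdm.matrix[iu]
    if not same.any() or same.all():
        raise ValueError("concept_map must yield both within- and between-concept pairs")
    return DissimSummary(
        dissim_w=float(vals[same].mean()), dissim_b=float(vals[~same].mean())
    )


def dissim_diff_permutation_null(
    rdm: RDM, concept_map: np.ndarray, n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """DissimDiff under shuffled concept assignments (sanity-check null)."""
    if rng is None:
        rng = np.random.default_rng(0)
    concept_map = np.asarray(concept_map)
    out = np.empty(n_perm)
    for i in range(n_perm):
        s = dissim_summary(rdm, rng.permutation(concept_map))
        out[i] = s.dissim_diff
    return out


# ---------------------------------------------------------------------------
# Experiment-level tidy summaries
# ---------------------------------------------------------------------------


def summarize_experiment(results: ExperimentResults) -> pd.DataFrame:
    """Tidy per-model, per-area dissimilarity table.

    Columns: subject, semantic_type, label, area, dissim_w, dissim_b,
    dissim_diff.  Rows cover the 12 areas for every design cell present.
    """
    rows = []
    for (subj, semantic_type, label), rm in results.responses.items():
        for area in AREA_NAMES:
            s = dissim_summary(compute_rdm(rm, area), rm.concept_of)
            rows.append(
                (subj, semantic_type, label, area, s.dissim_w, s.dissim_b, s.dissim_diff)
            )
    return pd.DataFrame(
        rows,
        columns=["subject", "semantic_type", "label", "area",
                 "dissim_w", "dissim_b", "dissim_diff"],
    ).sort_values(["subject", "semantic_type", "label", "area"]).reset_index(drop=True)


def collapse_areas(summary: pd.DataFrame) -> pd.DataFrame:
    """Mean of each measure over all 12 areas, per subject × condition."""
    return (
        summary.groupby(["subject", "semantic_type", "label"], as_index=False)[
            list(MEASURES)
        ].mean()
    )


def label_effect(
    summary: pd.DataFrame,
    measure: str,
    by: tuple[str, ...] = ("subject", "semantic_type", "area"),
) -> pd.DataFrame:
    """Per-subject percentage change from the no-label to the label condition.

    Computed as 100 · (label − no_label) / no_label within each group of
    ``by`` columns.  Groups with a zero no-label baseline are dropped with
    a logged warning.
    """
    if measure not in summary.columns:
        raise ValueError(f"unknown measure {measure!r}")
    by = tuple(c for c in by if c in summary.columns)
    wide = summary.pivot_table(index=list(by), columns="label", values=measure)
    if "label" not in wide.columns or "no-label" not in wide.columns:
        raise ValueError("summary must contain both label levels")
    zero = wide["no-label"] == 0.0
    if zero.any():
        log.warning(
            "dropping %d group(s) with zero no-label baseline for %s",
            int(zero.sum()), measure,
        )
        wide = wide[~zero]
    out = wide.reset_index()
    out["effect_pct"] = 100.0 * (out["label"] - out["no-label"]) / out["no-label"]
    out["measure"] = measure
    return out.drop(columns=["label", "no-label"])


def aggregate_label_effect(effects: pd.DataFrame, by: tuple[str, ...] = ("semantic_type",)) -> pd.DataFrame:
    """Mean label effect across subjects with a t-based 95% CI."""
    def _agg(g: pd.Series) -> pd.Series:
        n = g.size
        m = g.mean()
        if n > 1:
            half = scipy.stats.t.ppf(0.975, n - 1) * g.std(ddof=1) / np.sqrt(n)
        else:
            half = np.nan
        return pd.Series({"mean_pct": m, "ci95_lo": m - half, "ci95_hi": m + half, "n": n})

    return (
        effects.groupby(list(by))["effect_pct"].apply(_agg).unstack().reset_index()
    )


# ---------------------------------------------------------------------------
# Repeated-measures statistics
# ---------------------------------------------------------------------------


def rm_anova(values: pd.DataFrame, factors: list[str], depvar: str = "value",
             subject: str = "subject") -> pd.DataFrame:
    """Fully within-subject ANOVA for 2–3 two-level factors.

    ``values`` is a long table with one row per subject × factor cell
    (complete and balanced).  Returns a table with F, degrees of freedom
    and p per main effect and interaction; each error term has (n − 1)
    numerator-matched df for two-level factors.
    """
    from statsmodels.stats.anova import AnovaRM

    if not 2 <= len(factors) <= 3:
        raise ValueError("rm_anova supports 2 or 3 within-subject factors")
    cells = values.groupby(factors).size()
    n_subj = values[subject].nunique()
    if (cells != n_subj).any():
        raise ValueError("incomplete or unbalanced design (missing cells)")
    res = AnovaRM(values, depvar=depvar, subject=subject, within=list(factors)).fit()
    tab = res.anova_table.rename(
        columns={"F Value": "F", "Num DF": "df_num", "Den DF": "df_den", "Pr > F": "p"}
    )
    tab.index.name = "effect"
    return tab.reset_index()


def posthoc_paired_tests(
    contrasts: dict[str, tuple[np.ndarray, np.ndarray]],
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Paired t-tests with Bonferroni correction over the contrast family."""
    if correction != "bonferroni":
        raise ValueError("only Bonferroni correction is supported")
    m = len(contrasts)
    rows = []
    for name, (a, b) in contrasts.items():
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.size != b.size or a.size < 2:
            raise ValueError(f"contrast {name!r} needs ≥ 2 paired samples")
        if np.allclose(a, b):
            t, p = 0.0, 1.0
        else:
            t, p = scipy.stats.ttest_rel(a, b)
        rows.append((name, float(t), a.size - 1, float(p), float(min(1.0, p * m))))
    log.info("post-hoc family size m = %d", m)
    return pd.DataFrame(rows, columns=["contrast", "t", "df", "p_raw", "p_bonferroni"])


def centrality_rollup(
    summary: pd.DataFrame, include_secondary: bool = False
) -> pd.DataFrame:
    """Average measures over extrasylvian primary vs central areas.

    primary = mean over {*V1, *M1_L}; central = mean over {*AT, *PF_L};
    the secondary level (*TO, *PM_L) is only reported when asked for
    (plots), it does not enter the binary-centrality statistics.
    """
    groups = {
        "primary": EXTRASYLVIAN_PRIMARY,
        "central": EXTRASYLVIAN_CENTRAL,
    }
    if include_secondary:
        groups["secondary"] = ("*TO", "*PM_L")
    missing = [
        a for areas in groups.values() for a in areas
        if a not in set(summary["area"])
    ]
    if missing:
        raise ValueError(f"summary is missing areas {missing}")
    out = []
    keys = [c for c in ("subject", "semantic_type", "label") if c in summary.columns]
    value_cols = [c for c in summary.columns if c in MEASURES or c == "effect_pct"]
    for level, areas in groups.items():
        sub = summary[summary["area"].isin(areas)]
        agg = sub.groupby(keys, as_index=False)[value_cols].mean()
        agg.insert(len(keys), "centrality", level)
        out.append(agg)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# Plots (optional, basic)
# ---------------------------------------------------------------------------


def plot_rdm(rdm: RDM, ax=None):
    """Heat map of one RDM."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(rdm.matrix, cmap="viridis")
    ax.set_title(f"RDM {rdm.area}")
    ax.figure.colorbar(im, ax=ax, label="Euclidean distance")
    return ax


def plot_label_effect(effects: pd.DataFrame, ax=None):
    """Bar chart of mean label effects by semantic type (and centrality)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    keys = [c for c in ("centrality", "semantic_type") if c in effects.columns]
    agg = effects.groupby(keys)["effect_pct"].mean()
    agg.plot.bar(ax=ax)
    ax.set_ylabel("label effect (% of no-label baseline)")
    return ax
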