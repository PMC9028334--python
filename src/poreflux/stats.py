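"""Block-based statistical pipeline for channel trajectories.

Trajectories are divided into contiguous, start-anchored 10 ns blocks
per channel; each (condition, channel, block) row of the BlockTable
carries the observables (water counts, pf, H-bond counts, distances).
A block is "functional" when at least 5 waters crossed the full 30 Å
section within it. Downstream: χ² association between binary factors,
parametric/non-parametric group comparison with an explicit decision
rule (Shapiro normality and Levene homoscedasticity at α = 0.05), and
slice-wise Spearman correlation of dipole z-angles conditioned on the
ligand's z position.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "FUNCTIONAL_THRESHOLD",
    "build_block_table",
    "classify_blocks",
    "ContingencyResult",
    "contingency_chi2",
    "ComparisonResult",
    "compare_groups",
    "slice_dipole_correlation",
    "build_report",
    "write_report",
]

#: Waters that must cross the 30 Å section in a 10 ns block for the
#: channel to be called functional (inclusive threshold).
FUNCTIONAL_THRESHOLD = 5


def build_block_table(records: list[dict], block_length: float = 10.0) -> pd.DataFrame:
    """Assemble a BlockTable from per-(condition, channel) block records.

    Each record is a dict with keys ``condition``, ``channel_id`` and
    observable arrays of equal per-block length (e.g.
    ``water_count_30A``). Returns a tidy DataFrame with one row per
    (condition, channel_id, block_index).
    """
    frames = []
    for rec in records:
        cond = rec["condition"]
        chan = rec["channel_id"]
        if cond is None or (isinstance(cond, float) and np.isnan(cond)):
            raise ValueError("missing condition label")
        obs = {k: np.asarray(v) for k, v in rec.items() if k not in ("condition", "channel_id")}
        lengths = {len(v) for v in obs.values()}
        if len(lengths) != 1:
            raise ValueError(f"observable arrays of unequal length: {lengths}")
        (n_blocks,) = lengths
        df = pd.DataFrame(obs)
        df.insert(0, "block_index", np.arange(n_blocks))
        df.insert(0, "channel_id", chan)
        df.insert(0, "condition", cond)
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    table.attrs["block_length_ns"] = block_length
    return table


def classify_blocks(
    table: pd.DataFrame,
    threshold: int = FUNCTIONAL_THRESHOLD,
    count_column: str = "water_count_30A",
) -> pd.DataFrame:
    """Call the functional state of every block: count ≥ threshold.

    The threshold is inclusive ("5 or more"). Returns a copy of the
    table with a boolean ``functional`` column.
    """
    if count_column not in table.columns:
        raise ValueError(f"column {count_column!r} not in table")
    calls = table.copy()
    calls["functional"] = calls[count_column] >= threshold
    return calls


@dataclass
class ContingencyResult:
    """2×2 association between two binary factors."""

    table: np.ndarray  # rows: factor A (False, True); cols: factor B
    chi2: float
    p_value: float
    dof: int
    correction: bool
    row_factor: str = ""
    col_factor: str = ""


def contingency_chi2(
    calls,
    row: str = "functional",
    col: str = "hbond_to_arginine",
    correction: bool = False,
) -> ContingencyResult:
    """Pearson χ² on a 2×2 contingency table.

    ``calls`` is either a DataFrame with boolean columns ``row`` and
    ``col`` (rows/cols ordered False, True) or a ready 2×2 count array.
    Yates continuity correction is off by default. A zero margin makes
    the association undefined and raises.
    """
    if isinstance(calls, pd.DataFrame):
        for c in (row, col):
            if c not in calls.columns:
                raise ValueError(f"column {c!r} not in calls")
        tab = (
            pd.crosstab(calls[row].astype(bool), calls[col].astype(bool))
            .reindex(index=[False, True], columns=[False, True], fill_value=0)
            .to_numpy()
        )
    else:
        tab = np.asarray(calls, dtype=float)
        if tab.shape != (2, 2):
            raise ValueError(f"expected a 2x2 table, got {tab.shape}")
    if tab.sum() < 1:
        raise ValueError("empty contingency table")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("zero margin: association undefined")
    chi2, p, dof, _ = sps.chi2_contingency(tab, correction=correction)
    return ContingencyResult(
        table=tab,
        chi2=float(chi2),
        p_value=float(p),
        dof=int(dof),
        correction=correction,
        row_factor=row,
        col_factor=col,
    )


@dataclass
class ComparisonResult:
    """Outcome of the test-selection rule on ≥2 groups."""

    test_name: str
    statistic: float
    p_value: float
    group_labels: list
    normality_p: dict
    homoscedasticity_p: float | None
    parametric: bool
    correction: str | None = None
    posthoc: pd.DataFrame | None = field(default=None, repr=False)


def _is_constant(x: np.ndarray) -> bool:
    return np.ptp(x) == 0


def compare_groups(
    data,
    groups,
    paired: bool = False,
    alpha_normality: float = 0.05,
    alpha_variance: float = 0.05,
) -> ComparisonResult:
    """Compare ≥2 groups with the normality/homoscedasticity decision rule.

    Shapiro–Wilk is run per group and Levene across groups, both at
    α = 0.05. If every group is normal and variances are homogeneous:
    Student's t-test (2 groups) or one-way ANOVA with Tukey's post hoc
    (>2). Otherwise: Mann–Whitney (2) or pairwise Wilcoxon rank-sum
    tests with Bonferroni correction (>2). A constant group forces the
    non-parametric branch (Shapiro is undefined there); fully identical
    data short-circuits to p = 1.
    """
    data = np.asarray(data, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [data[groups == g] for g in labels]
    if any(len(s) < 3 for s in samples):
        raise ValueError("every group needs n >= 3")

    if _is_constant(data):
        return ComparisonResult(
            test_name="degenerate (all values identical)",
            statistic=0.0,
            p_value=1.0,
            group_labels=labels,
            normality_p={lab: np.nan for lab in labels},
            homoscedasticity_p=np.nan,
            parametric=False,
        )

    normality_p: dict = {}
    parametric = True
    for lab, s in zip(labels, samples):
        if _is_constant(s):
            logger.info("group %r is constant: forcing non-parametric branch", lab)
            normality_p[lab] = np.nan
            parametric = False
        else:
            normality_p[lab] = float(sps.shapiro(s).pvalue)
            if normality_p[lab] < alpha_normality:
                parametric = False
    try:
        lev_p = float(sps.levene(*samples).pvalue)
    except ValueError:
        lev_p = np.nan
    if not np.isnan(lev_p) and lev_p < alpha_variance:
        parametric = False

    if len(labels) == 2:
        a, b = samples
        if parametric:
            if paired:
                stat, p = sps.ttest_rel(a, b)
                name = "paired t-test"
            else:
                stat, p = sps.ttest_ind(a, b)
                name = "Student's t-test"
        else:
            if paired:
                stat, p = sps.wilcoxon(a, b)
                name = "Wilcoxon signed-rank"
            else:
                stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
                name = "Mann-Whitney U"
        return ComparisonResult(
            test_name=name,
            statistic=float(stat),
            p_value=float(p),
            group_labels=labels,
            normality_p=normality_p,
            homoscedasticity_p=lev_p,
            parametric=parametric,
        )

    # more than two groups
    if parametric:
        stat, p = sps.f_oneway(*samples)
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        tk = pairwise_tukeyhsd(data, groups)
        posthoc = pd.DataFrame(
            tk.summary().data[1:], columns=tk.summary().data[0]
        )
        return ComparisonResult(
            test_name="one-way ANOVA + Tukey HSD",
            statistic=float(stat),
            p_value=float(p),
            group_labels=labels,
            normality_p=normality_p,
            homoscedasticity_p=lev_p,
            parametric=True,
            correction="tukey",
            posthoc=posthoc,
        )

    rows = []
    n_pairs = len(labels) * (len(labels) - 1) // 2
    for la, lb in itertools.combinations(labels, 2):
        a = data[groups == la]
        b = data[groups == lb]
        stat, p = sps.ranksums(a, b)
        rows.append(
            {
                "group1": la,
                "group2": lb,
                "statistic": float(stat),
                "p_raw": float(p),
                "p_bonferroni": float(min(1.0, p * n_pairs)),
            }
        )
    posthoc = pd.DataFrame(rows)
    best = posthoc.loc[posthoc["p_bonferroni"].idxmin()]
    return ComparisonResult(
        test_name="pairwise Wilcoxon rank-sum + Bonferroni",
        statistic=float(best["statistic"]),
        p_value=float(best["p_bonferroni"]),
        group_labels=labels,
        normality_p=normality_p,
        homoscedasticity_p=lev_p,
        parametric=False,
        correction="bonferroni",
        posthoc=posthoc,
    )


def slice_dipole_correlation(
    protein_angles,
    ligand_angles,
    ligand_z,
    slab_width: float = 10.0,
    z_range: tuple[float, float] | None = None,
    min_frames: int = 5,
) -> pd.DataFrame:
    """Per-slab Spearman rho between two dipole z-angle series.

    Frames are assigned to 10 Å z-slabs by the ligand's center-of-
    geometry z; within each slab, Spearman's rank correlation between
    the protein and ligand angle series restricted to those frames.
    Slabs with fewer than ``min_frames`` frames are reported with
    status "insufficient data" instead of a coefficient.
    """
    protein_angles = np.asarray(protein_angles, dtype=float)
    ligand_angles = np.asarray(ligand_angles, dtype=float)
    ligand_z = np.asarray(ligand_z, dtype=float)
    if not (len(protein_angles) == len(ligand_angles) == len(ligand_z)):
        raise ValueError("angle and z series must be aligned in time")
    if z_range is None:
        lo = np.floor(ligand_z.min() / slab_width) * slab_width
        hi = np.ceil(ligand_z.max() / slab_width) * slab_width
    else:
        lo, hi = z_range
    edges = np.arange(lo, hi + slab_width / 2, slab_width)

    rows = []
    for s_lo, s_hi in zip(edges[:-1], edges[1:]):
        in_slab = (ligand_z >= s_lo) & (ligand_z < s_hi)
        n = int(in_slab.sum())
        if n < min_frames:
            rows.append(
                {"z_lo": s_lo, "z_hi": s_hi, "n_frames": n, "rho": np.nan,
                 "p_value": np.nan, "status": "insufficient data"}
            )
            continue
        rho, p = sps.spearmanr(protein_angles[in_slab], ligand_angles[in_slab])
        rows.append(
            {"z_lo": s_lo, "z_hi": s_hi, "n_frames": n, "rho": float(rho),
             "p_value": float(p), "status": "ok"}
        )
    return pd.DataFrame(rows)


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, (np.ndarray,)):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "__dataclass_fields__"):
        return {
            k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__
        }
    return obj


def build_report(results: dict, provenance: dict | None = None) -> dict:
    """Assemble a JSON-serialisable analysis report.

    ``results`` maps table names (e.g. "permeability_comparison",
    "contingency", "per_channel_pf", "block_tests",
    "slab_correlations") to DataFrames, dataclass results or plain
    values; ``provenance`` records inputs, parameters, seeds. Identical
    inputs produce byte-identical reports.
    """
    import poreflux

    report = {
        "provenance": {
            "package": "poreflux",
            "version": getattr(poreflux, "__version__", "unknown"),
            **(provenance or {}),
        },
        "tables": {name: _jsonable(val) for name, val in sorted(results.items())},
    }
    return report


def write_report(report: dict, directory) -> None:
    """Write a report as report.json plus one CSV per tabular entry."""
    import pathlib

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    for name, table in report.get("tables", {}).items():
        if isinstance(table, list) and table and isinstance(table[0], dict):
            pd.DataFrame(table).to_csv(directory / f"{name}.csv", index=False)
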