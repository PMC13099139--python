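"""Arrayed-screen hit calling: well aggregation, robust-Z normalisation,
replicate combination, exclusion filters, phenotype classification, and
cross-screen concordance.

The analysis path mirrors the standard high-content screening convention:
per-cell features are averaged per well over QC-passing nuclei; per-well
values are normalised per plate against the median of the library (gene)
wells using a robust Z-score, Z = (x - median) / (1.4826 * MAD); the
per-plate Z values of each biological replicate are pooled and standardised
again with the same robust Z; replicate Z-scores are averaged per gene.
Hits are genes whose mean Z magnitude strictly exceeds 2.5 on the
clustering score or the spot count, after excluding genes dominated by
dysmorphic nuclei, cytotoxic genes (cell-number Z < -2.5), and genes whose
mean Z is smaller in magnitude than the SD across replicates.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

Z_HIT_DEFAULT = 2.5
Z_CYTOTOXIC_DEFAULT = -2.5
MIN_CELLS_DEFAULT = 20
DYSMORPHIC_FRACTION_DEFAULT = 0.5

#: feature name -> well-summary column carrying it
FEATURE_COLUMNS = {
    "clustering": "mean_clustering_score",
    "count": "mean_spot_count",
    "cellnumber": "n_cells_pass_qc",
    "area": "mean_nuclear_area",
    "radial": "mean_radial_distance",
}

HIT_FEATURES = ("clustering", "count")

_CELL_FEATURES = {
    "mean_spot_count": "spot_count",
    "mean_clustering_score": "clustering_score",
    "mean_radial_distance": "radial_distance",
    "mean_nuclear_area": "nuclear_area",
}


def aggregate_wells(
    cells: pd.DataFrame, layout: pd.DataFrame, min_cells: int = MIN_CELLS_DEFAULT
) -> pd.DataFrame:
    """Per-well summary over QC-passing cells.

    One row per (plate, well, replicate): arithmetic feature means over
    qc_pass cells, the passing-cell count, the QC failure fraction, and a
    ``usable`` flag (False when fewer than ``min_cells`` cells pass QC).
    Wells in the layout with no cells at all appear with zero counts.
    """
    required = {"plate", "well", "replicate"}
    if not required <= set(cells.columns):
        raise ValueError(f"cell table must carry columns {sorted(required)}")
    keyed_layout = layout.set_index(["plate", "well"])
    bad = ~cells.set_index(["plate", "well"]).index.isin(keyed_layout.index)
    if bad.any():
        first = cells.loc[bad, ["plate", "well"]].iloc[0]
        raise ValueError(
            f"cell references well not in layout: plate {first['plate']} well {first['well']}"
        )

    replicates = sorted(cells["replicate"].unique())
    frames = []
    for rep in replicates:
        f = layout.copy()
        f["replicate"] = rep
        frames.append(f)
    out = pd.concat(frames, ignore_index=True)

    grp = cells.groupby(["plate", "well", "replicate"], sort=False)
    n_total = grp.size().rename("n_cells_total")
    ok = cells[cells["qc_pass"]]
    grp_ok = ok.groupby(["plate", "well", "replicate"], sort=False)
    n_pass = grp_ok.size().rename("n_cells_pass_qc")
    means = grp_ok[list(_CELL_FEATURES.values())].mean()
    means.columns = list(_CELL_FEATURES)

    out = out.set_index(["plate", "well", "replicate"])
    out = out.join(n_total).join(n_pass).join(means)
    out["n_cells_total"] = out["n_cells_total"].fillna(0).astype(int)
    out["n_cells_pass_qc"] = out["n_cells_pass_qc"].fillna(0).astype(int)
    out["qc_fail_fraction"] = np.where(
        out["n_cells_total"] > 0,
        1.0 - out["n_cells_pass_qc"] / out["n_cells_total"].clip(lower=1),
        np.nan,
    )
    out["usable"] = out["n_cells_pass_qc"] >= min_cells
    return out.reset_index()


def _robust_center_scale(values: np.ndarray, robust: bool = True):
    """(center, scale) for Z-scoring: median/1.4826*MAD, falling back to the
    SD when the MAD degenerates, and to scale 0 when everything is equal."""
    if robust:
        center = float(np.median(values))
        scale = 1.4826 * float(np.median(np.abs(values - center)))
        if scale == 0:
            scale = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    else:
        center = float(np.mean(values))
        scale = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return center, scale


def normalize_plate(
    wells: pd.DataFrame, feature: str, robust: bool = True, min_library_wells: int = 8
) -> pd.Series:
    """Per-plate robust Z of one feature, centred on the library wells.

    Center and scale come from usable library-role wells only, so extreme
    control wells never distort the normalisation; control wells receive Z
    values against the library center. Works on a table spanning several
    plates/replicates by grouping on (replicate, plate). Unusable wells get
    NaN.
    """
    col = FEATURE_COLUMNS.get(feature, feature)
    z = pd.Series(np.nan, index=wells.index, name=f"z_{feature}")
    for (rep, plate), idx in wells.groupby(["replicate", "plate"]).groups.items():
        sub = wells.loc[idx]
        lib = sub[(sub["role"] == "library") & sub["usable"]]
        if len(lib) < min_library_wells:
            raise ValueError(
                f"plate {plate} replicate {rep}: {len(lib)} usable library wells "
                f"(need >= {min_library_wells})"
            )
        center, scale = _robust_center_scale(lib[col].to_numpy(float), robust)
        usable = sub["usable"]
        if scale == 0:
            warnings.warn(
                f"plate {plate} replicate {rep}: zero spread in library wells; all Z set to 0"
            )
            z.loc[idx] = np.where(usable, 0.0, np.nan)
        else:
            z.loc[idx] = np.where(usable, (sub[col] - center) / scale, np.nan)
    return z


def standardize_replicate(
    z: pd.Series, wells: pd.DataFrame, robust: bool = True
) -> pd.Series:
    """Second-stage robust Z: pool the per-plate Z values of one replicate
    across plates and standardise against the pooled library wells."""
    out = pd.Series(np.nan, index=wells.index, name=z.name)
    for rep, idx in wells.groupby("replicate").groups.items():
        sub_z = z.loc[idx]
        lib_sel = (wells.loc[idx, "role"] == "library") & sub_z.notna()
        lib = sub_z[lib_sel].to_numpy(float)
        if len(lib) < 8:
            raise ValueError(f"replicate {rep}: too few usable library wells")
        center, scale = _robust_center_scale(lib, robust)
        if scale == 0:
            warnings.warn(f"replicate {rep}: zero spread; all Z set to 0")
            out.loc[idx] = np.where(sub_z.notna(), 0.0, np.nan)
        else:
            out.loc[idx] = (sub_z - center) / scale
    return out


def compute_well_z(
    wells: pd.DataFrame,
    features=("clustering", "count", "cellnumber", "area"),
    robust: bool = True,
) -> pd.DataFrame:
    """Two-stage (plate, then replicate) robust Z for each feature,
    appended as ``z_<feature>`` columns."""
    out = wells.copy()
    for feat in features:
        z_plate = normalize_plate(out, feat, robust=robust)
        out[f"z_{feat}"] = standardize_replicate(z_plate, out, robust=robust)
    return out


def combine_replicates(
    well_z: pd.DataFrame, features=("clustering", "count", "cellnumber", "area")
) -> pd.DataFrame:
    """Average Z-scores for the same (plate, well) across replicates.

    Genes occupy one well per plate, so this yields one row per gene (and
    per control role instance). Emits mean and across-replicate SD per
    feature; genes missing a usable value in any replicate are flagged
    ``incomplete`` and excluded from hit calling.
    """
    n_reps = well_z["replicate"].nunique()
    if n_reps == 1:
        warnings.warn("single replicate: SD undefined, consistency filter will be skipped")
    grp = well_z.groupby(["plate", "well"], sort=False)
    first = grp[["role", "gene"]].first()
    rows = {"role": first["role"], "gene": first["gene"]}
    for feat in features:
        col = f"z_{feat}"
        rows[f"mean_z_{feat}"] = grp[col].mean()
        rows[f"sd_z_{feat}"] = grp[col].std(ddof=1)
        rows[f"n_rep_{feat}"] = grp[col].count()
    rows["qc_fail_fraction"] = grp["qc_fail_fraction"].mean()
    out = pd.DataFrame(rows).reset_index()
    out["incomplete"] = False
    for feat in features:
        out["incomplete"] |= out[f"n_rep_{feat}"] < n_reps
    return out


def call_hits(
    gene_z: pd.DataFrame,
    z_hit: float = Z_HIT_DEFAULT,
    z_cytotoxic: float = Z_CYTOTOXIC_DEFAULT,
    dysmorphic_fraction: float = DYSMORPHIC_FRACTION_DEFAULT,
) -> pd.DataFrame:
    """Apply exclusion filters and the hit definition.

    Exclusion precedence (each gene gets exactly one reason or none):

    1. ``dysmorphic`` — more than half of the gene's nuclei fail QC;
    2. ``cytotoxic`` — mean cell-number Z strictly below -2.5;
    3. ``inconsistent`` — every feature whose |mean Z| exceeds the hit
       threshold has |mean Z| smaller than its across-replicate SD.

    Remaining genes are hits iff |mean Z| strictly exceeds 2.5 on the
    clustering score or the spot count (only features surviving the
    consistency check qualify). Directions derive from the sign of the
    qualifying mean Z. Only library wells are eligible; control wells are
    carried through with hit=False.
    """
    out = gene_z.copy()
    reasons = np.array(["none"] * len(out), dtype=object)
    hit = np.zeros(len(out), dtype=bool)
    clustering_dir = np.array(["none"] * len(out), dtype=object)
    count_dir = np.array(["none"] * len(out), dtype=object)

    single_rep = bool((out.get("sd_z_clustering") is not None) and out["sd_z_clustering"].isna().all())

    for i, row in enumerate(out.itertuples(index=False)):
        if row.role != "library":
            continue
        if getattr(row, "incomplete", False):
            reasons[i] = "incomplete"
            continue
        if row.qc_fail_fraction > dysmorphic_fraction:
            reasons[i] = "dysmorphic"
            continue
        if row.mean_z_cellnumber < z_cytotoxic:
            reasons[i] = "cytotoxic"
            continue
        qualifying = [
            f for f in HIT_FEATURES if abs(getattr(row, f"mean_z_{f}")) > z_hit
        ]
        if not qualifying:
            continue
        if single_rep:
            surviving = qualifying
        else:
            surviving = [
                f
                for f in qualifying
                if abs(getattr(row, f"mean_z_{f}")) >= getattr(row, f"sd_z_{f}")
            ]
        if not surviving:
            reasons[i] = "inconsistent"
            continue
        hit[i] = True
        if "clustering" in surviving:
            clustering_dir[i] = (
                "clustered" if row.mean_z_clustering > 0 else "unclustered"
            )
        if "count" in surviving:
            count_dir[i] = "higher" if row.mean_z_count > 0 else "lower"

    out["excluded_reason"] = reasons
    out["hit"] = hit
    out["clustering_direction"] = clustering_dir
    out["count_direction"] = count_dir
    return out


def classify_phenotype(call) -> str:
    """Phenotype category of a hit.

    Combines the clustering-score and spot-count directions: a higher
    clustering score with fewer spots means tighter clustering; the
    opposite signs mean dispersion; a joint decrease suggests fewer but
    larger local clusters. Raises on non-hits.
    """
    if isinstance(call, pd.Series):
        call = call.to_dict()
    elif not isinstance(call, dict):
        call = call._asdict() if hasattr(call, "_asdict") else vars(call)
    if not call.get("hit", False):
        raise ValueError("phenotype classification applies to hits only")
    cd = call.get("clustering_direction", "none")
    nd = call.get("count_direction", "none")
    if cd != "none" and nd != "none":
        key = (cd, nd)
        return {
            ("clustered", "lower"): "higher clustering",
            ("unclustered", "higher"): "dispersion",
            ("unclustered", "lower"): "fewer larger clusters",
            ("clustered", "higher"): "more numerous clustered spots",
        }[key]
    if cd != "none":
        return f"clustering-only ({cd})"
    return f"count-only ({nd})"


@dataclass
class ConcordanceReport:
    """Cross-screen comparison of per-gene clustering Z-scores."""

    pearson_r: float
    p_value: float
    n_genes: int
    common_hits: list
    direction_agreement: pd.DataFrame

    def __str__(self):
        lines = [
            f"genes compared: {self.n_genes}",
            f"Pearson R (mean clustering Z): {self.pearson_r:.3f} (p={self.p_value:.3g})",
            f"common hits: {len(self.common_hits)}",
        ]
        if len(self.direction_agreement):
            same = (self.direction_agreement["clustering_agreement"] == "same").sum()
            lines.append(f"clustering direction same in {same}/{len(self.direction_agreement)}")
        return "\n".join(lines)


def _direction_agreement(a: str, b: str) -> str:
    if a == "none" or b == "none":
        return "n/a"
    return "same" if a == b else "opposite"


def compare_cell_lines(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> ConcordanceReport:
    """Concordance of two screens sharing a gene universe.

    Pearson correlation of mean clustering Z over genes not excluded in
    either screen, the intersection of hit sets, and per-common-hit
    direction agreement for clustering and count.
    """
    a = calls_a[calls_a["role"] == "library"].set_index("gene")
    b = calls_b[calls_b["role"] == "library"].set_index("gene")
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("screens share no genes")
    a = a.loc[shared]
    b = b.loc[shared]
    ok = (a["excluded_reason"] == "none") & (b["excluded_reason"] == "none")
    r, p = stats.pearsonr(
        a.loc[ok, "mean_z_clustering"], b.loc[ok, "mean_z_clustering"]
    )
    common = sorted(set(a.index[a["hit"]]) & set(b.index[b["hit"]]))
    rows = []
    for g in common:
        rows.append(
            {
                "gene": g,
                "clustering_agreement": _direction_agreement(
                    a.loc[g, "clustering_direction"], b.loc[g, "clustering_direction"]
                ),
                "count_agreement": _direction_agreement(
                    a.loc[g, "count_direction"], b.loc[g, "count_direction"]
                ),
            }
        )
    return ConcordanceReport(
        pearson_r=float(r),
        p_value=float(p),
        n_genes=int(ok.sum()),
        common_hits=common,
        direction_agreement=pd.DataFrame(
            rows, columns=["gene", "clustering_agreement", "count_agreement"]
        ),
    )


def significance_stars(p: float) -> str:
    """Star convention: * p<=0.05, ** p<=0.01, *** p<=0.001, **** p<0.0001."""
    if p < 0.0001:
        return "****"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def compare_groups(values, group_labels, method: str = "anova_tukey") -> pd.DataFrame:
    """Group comparisons with the reporting conventions used throughout.

    ``anova_tukey`` runs a one-way ANOVA followed by Tukey's HSD on all
    pairs; ``pairwise_t_bonferroni`` runs all pairwise Welch t-tests with
    Bonferroni-adjusted p-values (raw p times the number of comparisons,
    capped at 1). Returns one row per pair with the adjusted p-value and
    significance stars.
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    groups = pd.unique(group_labels)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if (group_labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")

    if method == "anova_tukey":
        res = pairwise_tukeyhsd(values, group_labels)
        frame = pd.DataFrame(
            res.summary().data[1:], columns=[c.strip() for c in res.summary().data[0]]
        )
        out = pd.DataFrame(
            {
                "group1": frame["group1"],
                "group2": frame["group2"],
                "statistic": frame["meandiff"].astype(float),
                "p_adj": frame["p-adj"].astype(float),
            }
        )
    elif method == "pairwise_t_bonferroni":
        pairs = list(itertools.combinations(groups, 2))
        k = len(pairs)
        rows = []
        for g1, g2 in pairs:
            x = values[group_labels == g1]
            y = values[group_labels == g2]
            t, p = stats.ttest_ind(x, y, equal_var=False)
            rows.append(
                {
                    "group1": g1,
                    "group2": g2,
                    "statistic": float(t),
                    "p_adj": min(1.0, float(p) * k),
                }
            )
        out = pd.DataFrame(rows)
    else:
        raise ValueError(f"unknown method {method!r}")
    out["stars"] = out["p_adj"].map(significance_stars)
    return out


def run_screen_analysis(
    cells: pd.DataFrame,
    layout: pd.DataFrame,
    z_hit: float = Z_HIT_DEFAULT,
    z_cytotoxic: float = Z_CYTOTOXIC_DEFAULT,
    min_cells: int = MIN_CELLS_DEFAULT,
    robust: bool = True,
) -> dict:
    """Full per-cell-table -> GeneCall pipeline.

    Returns a dict with ``wells`` (per-well summaries with Z columns),
    ``gene_calls`` (one row per gene with mean Z, exclusions, hit flags)
    and ``hits`` (library hits only, with phenotype categories).
    """
    wells = aggregate_wells(cells, layout, min_cells=min_cells)
    well_z = compute_well_z(wells, robust=robust)
    gene_z = combine_replicates(well_z)
    calls = call_hits(gene_z, z_hit=z_hit, z_cytotoxic=z_cytotoxic)
    hits = calls[calls["hit"]].copy()
    if len(hits):
        hits["phenotype"] = hits.apply(classify_phenotype, axis=1)
    else:
        hits["phenotype"] = pd.Series(dtype=object)
    return {"wells": well_z, "gene_calls": calls, "hits": hits}
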