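"""Cell-cycle phase assignment from integrated DAPI and EdU intensities.

DNA content doubles from G1 (2N) to G2/M (4N), so the log2-transformed
integrated DAPI intensity of a cycling population is bimodal with modes one
unit apart. The gate locates the two modes, calls S phase from detectable
EdU incorporation, and excludes cells with DNA content below the G1 mode
(subG1, apoptotic debris) or above the G2/M mode (>4N, polyploid or
doublets).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from sklearn.mixture import GaussianMixture

PHASES = ("G1", "S", "G2M", "excluded")


@dataclass(frozen=True)
class PhaseGate:
    """Fitted intensity gates, all on the log2 scale."""

    log2_dapi_g1_mode: float
    log2_dapi_g2_mode: float
    g1_g2_cut: float
    subg1_cut: float
    over4n_cut: float
    edu_positive_cut: float
    edu_bimodal: bool

    def __post_init__(self):
        if not (
            self.subg1_cut
            < self.log2_dapi_g1_mode
            < self.g1_g2_cut
            < self.log2_dapi_g2_mode
            < self.over4n_cut
        ):
            raise ValueError("gate cut ordering violated")
        sep = self.log2_dapi_g2_mode - self.log2_dapi_g1_mode
        if not (0.7 <= sep <= 1.3):
            raise ValueError(
                f"G1/G2 mode separation {sep:.2f} incompatible with a DNA doubling"
            )


def _edu_cut(log2_edu: np.ndarray) -> tuple[float, bool]:
    """Threshold for 'detectable EdU'.

    Valley between the two dominant modes of the log2 EdU histogram when
    the distribution is bimodal; otherwise (no S population) a fallback cut
    placed above the background mode (99th percentile plus a 0.5 log2
    margin) so that no background cell is called S.
    """
    lo, hi = np.quantile(log2_edu, [0.001, 0.999])
    if hi - lo < 1e-6:
        return float(hi + 0.5), False
    hist, edges = np.histogram(log2_edu, bins=64, range=(lo, hi))
    smooth = gaussian_filter1d(hist.astype(float), 1.5)
    peaks, props = find_peaks(smooth, prominence=0.05 * smooth.max())
    centers = 0.5 * (edges[:-1] + edges[1:])
    if len(peaks) >= 2:
        # two largest peaks by height, in position order
        top = peaks[np.argsort(smooth[peaks])[-2:]]
        p_lo, p_hi = np.sort(top)
        if centers[p_hi] - centers[p_lo] >= 1.0:
            valley = p_lo + int(np.argmin(smooth[p_lo : p_hi + 1]))
            return float(centers[valley]), True
    return float(np.quantile(log2_edu, 0.99) + 0.5), False


def fit_gate(dapi_totals, edu_totals) -> PhaseGate:
    """Fit the phase gate from a population of integrated intensities.

    The EdU threshold is determined first; EdU-negative cells (G1 + G2/M,
    free of the S-phase bridge between the DNA-content modes) then feed a
    two-component Gaussian mixture on log2 DAPI with deterministic
    percentile initialisation. Cuts: G1/G2 at the midpoint of the modes,
    subG1/>4N at three component SDs outside the modes.

    Requires at least 200 cells and strictly positive intensities; raises
    if the DAPI distribution cannot be resolved into 2N and 4N modes.
    """
    dapi = np.asarray(dapi_totals, dtype=float)
    edu = np.asarray(edu_totals, dtype=float)
    if len(dapi) < 200:
        raise ValueError("gate fitting requires at least 200 cells")
    if (dapi <= 0).any() or (edu <= 0).any():
        raise ValueError("intensity totals must be positive")
    ld = np.log2(dapi)
    le = np.log2(edu)

    edu_cut, bimodal = _edu_cut(le)
    fit_vals = ld[le < edu_cut] if bimodal else ld
    # trim tails so subG1/>4N contaminants cannot drag the component fits
    q_lo, q_hi = np.quantile(fit_vals, [0.02, 0.98])
    fit_vals = fit_vals[(fit_vals >= q_lo) & (fit_vals <= q_hi)]
    if len(fit_vals) < 50:
        raise ValueError("too few EdU-negative cells to fit the DAPI mixture")

    init = np.quantile(fit_vals, [0.25, 0.75]).reshape(-1, 1)
    gmm = GaussianMixture(
        n_components=2,
        means_init=init,
        random_state=0,
        reg_covar=1e-6,
        max_iter=500,
    ).fit(fit_vals.reshape(-1, 1))
    means = gmm.means_.ravel()
    sds = np.sqrt(gmm.covariances_.ravel())
    order = np.argsort(means)
    g1_mode, g2_mode = means[order]
    sd1, sd2 = sds[order]
    if g2_mode - g1_mode < 0.5:
        raise ValueError("cannot resolve 2N/4N: DAPI mode separation < 0.5")

    return PhaseGate(
        log2_dapi_g1_mode=float(g1_mode),
        log2_dapi_g2_mode=float(g2_mode),
        g1_g2_cut=float(0.5 * (g1_mode + g2_mode)),
        subg1_cut=float(g1_mode - 3.0 * sd1),
        over4n_cut=float(g2_mode + 3.0 * sd2),
        edu_positive_cut=float(edu_cut),
        edu_bimodal=bimodal,
    )


def assign_phase(dapi_total: float, edu_total: float, gate: PhaseGate) -> str:
    """Phase label for a single cell (see :func:`assign_phases`)."""
    return assign_phases(np.array([dapi_total]), np.array([edu_total]), gate)[0]


def assign_phases(dapi_totals, edu_totals, gate: PhaseGate) -> np.ndarray:
    """Vectorised phase assignment.

    Exclusion wins first: DNA content outside [subg1_cut, over4n_cut] is
    never analysed. Among analysable cells, detectable EdU always means S
    regardless of DNA content; the rest split G1/G2M at the midpoint cut.
    """
    ld = np.log2(np.asarray(dapi_totals, dtype=float))
    le = np.log2(np.asarray(edu_totals, dtype=float))
    out = np.where(ld < gate.g1_g2_cut, "G1", "G2M")
    out = np.where(le >= gate.edu_positive_cut, "S", out)
    out = np.where((ld < gate.subg1_cut) | (ld > gate.over4n_cut), "excluded", out)
    return out.astype(object)


def gate_cells(
    cells: pd.DataFrame, per: str = "plate", min_cells: int = 200
) -> tuple[pd.DataFrame, dict]:
    """Fit gates on pooled populations and label every cell.

    ``per`` chooses the pooling unit for gate fitting: 'plate' (default,
    one gate per plate x replicate), 'replicate', or 'all'. Returns the
    cell table with a ``phase`` column plus the fitted gates keyed by
    pooling unit.
    """
    cells = cells.copy()
    if per == "all":
        keys = [()]
        groups = {(): cells.index}
    else:
        by = ["replicate", "plate"] if per == "plate" else ["replicate"]
        groups = cells.groupby(by).groups
        keys = list(groups)
    gates: dict = {}
    phase = pd.Series(index=cells.index, dtype=object)
    for key in keys:
        idx = groups[key]
        sub = cells.loc[idx]
        if len(sub) < min_cells:
            raise ValueError(f"pooling unit {key} has fewer than {min_cells} cells")
        gate = fit_gate(sub["dapi_total"].to_numpy(), sub["edu_total"].to_numpy())
        gates[key] = gate
        phase.loc[idx] = assign_phases(
            sub["dapi_total"].to_numpy(), sub["edu_total"].to_numpy(), gate
        )
    cells["phase"] = phase
    return cells, gates


def phase_summaries(cells: pd.DataFrame, feature: str = "clustering_score") -> pd.DataFrame:
    """Per-phase summary of a feature over QC-passing, analysable cells."""
    ok = cells[cells["qc_pass"] & (cells["phase"] != "excluded")]
    out = (
        ok.groupby("phase")[feature]
        .agg(["mean", "median", "std", "count"])
        .rename(columns={"count": "n_cells"})
    )
    return out.reset_index()
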