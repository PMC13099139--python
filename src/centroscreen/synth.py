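"""Synthetic-data generator for the centromere-distribution pipeline.

Emulates the statistical structure of a high-throughput imaging CRISPR
screen so every downstream stage (segmentation, spot detection, clustering
scoring, cell-cycle gating, hit calling) can be exercised against known
ground truth:

* elliptical nuclei of realistic area rendered at 0.108 µm/pixel, with
  optional boundary roughness to produce QC-failing dysmorphic shapes;
* per-nucleus spot point patterns placed by uniform (CSR), clustered
  (Thomas parent/offspring) or radially biased processes, always strictly
  inside the nuclear mask;
* rendered 16-bit multi-channel fields (DAPI, spots, optional EdU) with
  Gaussian point-spread and Poisson + Gaussian noise;
* whole 384-well arrayed screens at the feature level (per-cell tables)
  with 7 control wells per plate for each of the scrambled / PLK1 / OR10A5
  / NCAPH2 roles, two biological replicates, per-gene effect sizes, and
  ground-truth labels;
* DAPI/EdU intensity populations with a 2N/4N doubling, an EdU-positive
  S fraction, and subG1 / >4N contaminants.

Identical seeds reproduce identical datasets at every level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import polygon as draw_polygon
from skimage.measure import label as sk_label

from ._geometry import (
    mask_centroid,
    points_in_mask,
    ray_boundary_distance,
    sample_uniform_in_mask,
)
from .imaging import NucleusRecord, measure_nucleus
from .spatialstats import DEFAULT_N_MC, clustering_score

DEFAULT_PIXEL_SIZE = 0.108
DEFAULT_FIELD_SHAPE = (512, 512)

CONTROL_ROLES = ("scrambled", "PLK1", "OR10A5", "NCAPH2")


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class NucleusShapeParams:
    """Elliptical nucleus with optional low-order boundary roughness.

    Semi-axes are in µm; the default axes give an area of ~102 µm²,
    typical of an adherent near-diploid human cell. boundary_noise_amplitude
    is the fractional radial perturbation (0–0.3); large values yield lobed,
    low-solidity shapes useful as QC-fail fixtures.
    """

    semi_axis_a: float = 6.5
    semi_axis_b: float = 5.0
    orientation: float = 0.0
    centroid: tuple = (256.0, 256.0)
    boundary_noise_amplitude: float = 0.0

    def __post_init__(self):
        if not (self.semi_axis_a >= self.semi_axis_b > 0):
            raise ValueError("require semi_axis_a >= semi_axis_b > 0")
        if not (0.0 <= self.boundary_noise_amplitude <= 0.3):
            raise ValueError("boundary_noise_amplitude must be in [0, 0.3]")


@dataclass
class SpotProcessParams:
    """Ground-truth spot placement process.

    n_spots defaults to 46, one spot per chromosome of a diploid human
    karyotype. thomas_sigma is the offspring dispersion in µm;
    min_separation (µm) optionally enforces a hard core, producing
    resolvable spots for detection fixtures.
    """

    n_spots: int = 46
    process_kind: str = "csr"  # csr | thomas | radial_biased
    thomas_n_parents: int = 8
    thomas_sigma: float = 0.5
    radial_bias_exponent: float = 1.0
    min_separation: float | None = None

    def __post_init__(self):
        if self.n_spots < 0:
            raise ValueError("n_spots must be >= 0")
        if self.process_kind not in ("csr", "thomas", "radial_biased"):
            raise ValueError(f"unknown process kind {self.process_kind!r}")
        if self.process_kind == "thomas" and self.thomas_sigma <= 0:
            raise ValueError("thomas_sigma must be > 0 for a thomas process")


@dataclass
class CellCycleSimParams:
    """DAPI/EdU population structure.

    log2 DAPI is bimodal with the 4N mode exactly one unit above the 2N
    mode (DNA doubling); S-phase cells lie between the modes and carry EdU
    signal shifted ``edu_positive_log2_shift`` log2 units above background.
    subG1 and >4N contaminants are placed outside
    [G1 mode - 3 sd, G2 mode + 3 sd].
    """

    g1_fraction: float = 0.5
    s_fraction: float = 0.3
    g2m_fraction: float = 0.2
    dapi_2n_log2_mean: float = 10.0
    dapi_log2_sd: float = 0.12
    edu_background_log2_mean: float = 6.0
    edu_background_log2_sd: float = 0.2
    edu_positive_log2_shift: float = 2.5
    subg1_fraction: float = 0.01
    over4n_fraction: float = 0.02

    def __post_init__(self):
        fracs = [
            self.g1_fraction,
            self.s_fraction,
            self.g2m_fraction,
            self.subg1_fraction,
            self.over4n_fraction,
        ]
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("all fractions must lie in [0, 1]")
        if abs(self.g1_fraction + self.s_fraction + self.g2m_fraction - 1.0) > 1e-9:
            raise ValueError("G1 + S + G2M fractions must sum to 1")

    @property
    def dapi_4n_log2_mean(self) -> float:
        return self.dapi_2n_log2_mean + 1.0


@dataclass
class ScreenDesign:
    """Arrayed-screen layout and effect model.

    One gene per library well (three pooled sgRNAs per well in the emulated
    assay), the same layout in every biological replicate, and 7 control
    wells per plate for each control role. Per-gene effects are expressed
    in units of the null well-to-well SD for the clustering score and spot
    count (see ``null_well_sd``), plus a multiplicative effect on cell
    number (cytotoxicity) and an optional elevated QC-failure rate
    (dysmorphic nuclei).
    """

    n_genes: int = 1064
    n_plates: int | None = None
    wells_per_plate: int = 384
    n_replicates: int = 2
    control_wells_per_plate: dict = field(
        default_factory=lambda: {r: 7 for r in CONTROL_ROLES}
    )
    cells_per_well_mean: float = 200.0
    cells_per_well_dispersion: float = 10.0
    baseline_spot_count: float = 46.0
    well_effect_sd: float = 0.15  # clustering, per-cell-SD units
    well_count_effect_sd: float = 0.8  # spots
    baseline_qc_fail_rate: float = 0.05
    effect_table: pd.DataFrame | None = None
    cellcycle: CellCycleSimParams = field(default_factory=CellCycleSimParams)
    seed: int = 0

    @property
    def control_wells_total(self) -> int:
        return int(sum(self.control_wells_per_plate.values()))

    @property
    def library_wells_per_plate(self) -> int:
        n = self.wells_per_plate - self.control_wells_total
        if n <= 0:
            raise ValueError("control wells exceed plate capacity")
        return n

    @property
    def plates(self) -> int:
        if self.n_plates is not None:
            return self.n_plates
        return math.ceil(self.n_genes / self.library_wells_per_plate)

    @property
    def genes(self) -> list[str]:
        return [f"GENE{i + 1:04d}" for i in range(self.n_genes)]

    def resolved_effect_table(self) -> pd.DataFrame:
        """Effect table covering every library gene and control role."""
        if self.effect_table is None:
            eff = null_effect_table(self.genes, self.baseline_qc_fail_rate)
        else:
            eff = self.effect_table.copy()
            missing = set(self.genes) - set(eff.index)
            if missing:
                raise ValueError(
                    f"effect_table missing {len(missing)} genes, e.g. {sorted(missing)[:3]}"
                )
        controls = pd.DataFrame(
            {
                "clustering_shift": [0.0, 0.0, 0.0, 4.0],
                "count_shift": [0.0, 0.0, 0.0, -3.0],
                "cellnumber_multiplier": [1.0, 0.05, 1.0, 0.9],
                "qc_fail_rate": [self.baseline_qc_fail_rate] * 4,
            },
            index=["scrambled", "PLK1", "OR10A5", "NCAPH2"],
        )
        return pd.concat([eff, controls.loc[~controls.index.isin(eff.index)]])


def null_effect_table(genes, qc_fail_rate: float = 0.05) -> pd.DataFrame:
    """All-null per-gene effect table (zero shifts, neutral viability)."""
    return pd.DataFrame(
        {
            "clustering_shift": 0.0,
            "count_shift": 0.0,
            "cellnumber_multiplier": 1.0,
            "qc_fail_rate": qc_fail_rate,
        },
        index=pd.Index(genes, name="gene"),
    )


# ---------------------------------------------------------------------------
# nuclei and spots
# ---------------------------------------------------------------------------


def generate_nucleus_mask(
    params: NucleusShapeParams,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    field_shape: tuple = DEFAULT_FIELD_SHAPE,
    seed: int = 0,
) -> tuple[np.ndarray, NucleusRecord]:
    """Rasterise an (optionally roughened) elliptical nucleus.

    Returns the boolean mask and a NucleusRecord skeleton with geometry and
    morphology filled in (intensity totals zero). Raises if the shape does
    not fit inside the field.
    """
    rng = np.random.default_rng(seed)
    theta = np.linspace(0.0, 2.0 * np.pi, 720, endpoint=False)
    a_px = params.semi_axis_a / pixel_size
    b_px = params.semi_axis_b / pixel_size
    phi = params.orientation
    r = (a_px * b_px) / np.sqrt(
        (b_px * np.cos(theta - phi)) ** 2 + (a_px * np.sin(theta - phi)) ** 2
    )
    amp = params.boundary_noise_amplitude
    if amp > 0:
        harmonics = np.arange(2, 9)
        raw = np.zeros_like(theta)
        for k in harmonics:
            raw += rng.normal() * np.cos(k * theta) + rng.normal() * np.sin(k * theta)
        raw /= np.abs(raw).max()
        r = r * (1.0 + amp * raw)
    rows = params.centroid[0] + r * np.sin(theta)
    cols = params.centroid[1] + r * np.cos(theta)
    if (
        rows.min() < 0.5
        or cols.min() < 0.5
        or rows.max() > field_shape[0] - 1.5
        or cols.max() > field_shape[1] - 1.5
    ):
        raise ValueError("nucleus shape exceeds field bounds")
    rr, cc = draw_polygon(rows, cols, shape=field_shape)
    mask = np.zeros(field_shape, dtype=bool)
    mask[rr, cc] = True
    mask = ndi.binary_fill_holes(mask)
    labels = sk_label(mask)
    if labels.max() > 1:  # keep the largest component (roughness can pinch off slivers)
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        mask = labels == sizes.argmax()
    record = measure_nucleus(mask, pixel_size, nucleus_id=0)
    return mask, record


def _sample_one(mask, kind, params, rng, pixel_size, parents, centroid):
    """Draw a single point from the configured process (resampled until it
    lands inside the mask)."""
    if kind == "csr":
        return sample_uniform_in_mask(mask, 1, rng)[0]
    if kind == "thomas":
        sigma_px = params.thomas_sigma / pixel_size
        for _ in range(10000):
            parent = parents[rng.integers(0, len(parents))]
            p = parent + rng.normal(0.0, sigma_px, size=2)
            if points_in_mask(p, mask)[0]:
                return p
        raise RuntimeError("thomas offspring rejection sampling failed")
    # radial_biased: angle uniform, radius transformed by the bias exponent
    k = params.radial_bias_exponent
    for _ in range(10000):
        ang = rng.uniform(0.0, 2.0 * np.pi)
        direction = np.array([np.sin(ang), np.cos(ang)])
        b = ray_boundary_distance(mask, centroid, direction)
        r = b * rng.uniform() ** (1.0 / (2.0 * k))
        p = centroid + r * direction
        if points_in_mask(p, mask)[0]:
            return p
    raise RuntimeError("radial_biased rejection sampling failed")


def sample_spots(
    mask: np.ndarray,
    params: SpotProcessParams,
    seed: int = 0,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
) -> np.ndarray:
    """Sample exactly n_spots points strictly inside the mask.

    CSR points are uniform over mask pixels with sub-pixel jitter; Thomas
    offspring are Gaussian around uniformly placed parents, rejected and
    redrawn until inside the mask (keeping N exact); radially biased points
    transform the radial coordinate by the configured exponent. With
    ``min_separation`` set, candidates closer than that distance (µm) to an
    accepted point are redrawn (hard-core thinning).
    """
    mask = np.asarray(mask, dtype=bool)
    if params.n_spots == 0:
        return np.empty((0, 2), dtype=float)
    if not mask.any():
        raise ValueError("cannot place spots in an empty mask")
    rng = np.random.default_rng(seed)
    kind = params.process_kind

    parents = None
    centroid = None
    if kind == "thomas":
        parents = sample_uniform_in_mask(mask, params.thomas_n_parents, rng)
    elif kind == "radial_biased":
        centroid = mask_centroid(mask)

    min_sep_px = (
        params.min_separation / pixel_size if params.min_separation else None
    )

    if min_sep_px is None and kind == "csr":
        return sample_uniform_in_mask(mask, params.n_spots, rng)

    accepted = np.empty((params.n_spots, 2))
    n_acc = 0
    tries = 0
    while n_acc < params.n_spots:
        tries += 1
        if tries > 200000:
            raise RuntimeError("spot sampling failed: mask too small for the requested pattern")
        p = _sample_one(mask, kind, params, rng, pixel_size, parents, centroid)
        if min_sep_px is not None and n_acc > 0:
            d = np.hypot(*(accepted[:n_acc] - p).T)
            if (d < min_sep_px).any():
                continue
        accepted[n_acc] = p
        n_acc += 1
    return accepted


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def amplitude_for_snr(snr: float, background: float, gaussian_sd: float) -> float:
    """Peak amplitude giving the requested peak signal-to-noise ratio over a
    Poisson + Gaussian background."""
    return snr * float(np.sqrt(background + gaussian_sd**2))


def _add_gaussian(img: np.ndarray, row: float, col: float, sigma: float, amp: float):
    half = int(np.ceil(5 * sigma))
    r0 = max(0, int(np.floor(row)) - half)
    r1 = min(img.shape[0], int(np.ceil(row)) + half + 1)
    c0 = max(0, int(np.floor(col)) - half)
    c1 = min(img.shape[1], int(np.ceil(col)) + half + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    img[r0:r1, c0:c1] += amp * np.exp(
        -((rr - row) ** 2 + (cc - col) ** 2) / (2.0 * sigma**2)
    )


def render_field(
    nuclei_masks: list,
    spot_sets: list,
    psf_sigma: float = 1.5,
    background: float = 100.0,
    spot_amplitude: float = 1000.0,
    nuclear_intensity: float = 500.0,
    noise: bool = True,
    gaussian_sd: float = 2.0,
    phases: list | None = None,
    edu_intensity: dict | None = None,
    bit_depth: int = 16,
    seed: int = 0,
) -> dict:
    """Render a multi-channel field: filled nuclei (DAPI), 2D Gaussian spots
    at the true coordinates, and optionally a per-phase EdU channel.

    Noise is Poisson on the expected counts plus additive Gaussian read
    noise; output channels are clipped to the detector range and returned
    as uint16 (for the default bit depth).
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be > 0")
    shape = nuclei_masks[0].shape if nuclei_masks else DEFAULT_FIELD_SHAPE
    rng = np.random.default_rng(seed)
    max_val = 2**bit_depth - 1

    dapi = np.full(shape, float(background))
    for m in nuclei_masks:
        dapi[m] += nuclear_intensity

    spots = np.full(shape, float(background))
    for coords in spot_sets:
        for row, col in np.atleast_2d(coords):
            _add_gaussian(spots, row, col, psf_sigma, spot_amplitude)

    channels = {"dapi": dapi, "spots": spots}
    if phases is not None:
        if edu_intensity is None:
            edu_intensity = {"S": 400.0}
        edu = np.full(shape, float(background))
        for m, ph in zip(nuclei_masks, phases):
            edu[m] += edu_intensity.get(ph, 20.0)
        channels["edu"] = edu

    out = {}
    for name, clean in channels.items():
        if noise:
            img = rng.poisson(clean).astype(float) + rng.normal(0.0, gaussian_sd, shape)
        else:
            img = clean
        out[name] = np.clip(img, 0, max_val).astype(np.uint16)
    return out


def generate_image_well(
    n_nuclei: int = 6,
    shape_params: NucleusShapeParams | None = None,
    spot_params: SpotProcessParams | None = None,
    field_shape: tuple = DEFAULT_FIELD_SHAPE,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    snr: float = 10.0,
    background: float = 100.0,
    gaussian_sd: float = 2.0,
    noise: bool = True,
    seed: int = 0,
):
    """Render one field with ``n_nuclei`` non-touching nuclei and per-nucleus
    spot patterns; returns (channels, masks, spot_coords, records).

    Nuclei are laid out on a jittered grid so that segmentation ground truth
    is unambiguous. Used for image-level smoke paths and detection-fidelity
    fixtures.
    """
    shape_params = shape_params or NucleusShapeParams()
    spot_params = spot_params or SpotProcessParams()
    rng = np.random.default_rng(seed)
    ncols = int(np.ceil(np.sqrt(n_nuclei)))
    nrows = int(np.ceil(n_nuclei / ncols))
    cell_h = field_shape[0] / nrows
    cell_w = field_shape[1] / ncols
    a_px = shape_params.semi_axis_a / pixel_size
    if cell_h < 2.6 * a_px or cell_w < 2.6 * a_px:
        raise ValueError("field too small for the requested number of nuclei")
    masks, coords_list, records = [], [], []
    i = 0
    for gr in range(nrows):
        for gc in range(ncols):
            if i >= n_nuclei:
                break
            jitter = rng.uniform(-0.1, 0.1, size=2) * min(cell_h, cell_w)
            center = (
                (gr + 0.5) * cell_h + jitter[0],
                (gc + 0.5) * cell_w + jitter[1],
            )
            p = NucleusShapeParams(
                semi_axis_a=shape_params.semi_axis_a,
                semi_axis_b=shape_params.semi_axis_b,
                orientation=rng.uniform(0, np.pi),
                centroid=center,
                boundary_noise_amplitude=shape_params.boundary_noise_amplitude,
            )
            mask, rec = generate_nucleus_mask(
                p, pixel_size, field_shape, seed=int(rng.integers(2**31))
            )
            rec.nucleus_id = i
            masks.append(mask)
            records.append(rec)
            coords_list.append(
                sample_spots(mask, spot_params, seed=int(rng.integers(2**31)), pixel_size=pixel_size)
            )
            i += 1
    channels = render_field(
        masks,
        coords_list,
        spot_amplitude=amplitude_for_snr(snr, background, gaussian_sd),
        background=background,
        gaussian_sd=gaussian_sd,
        noise=noise,
        seed=int(rng.integers(2**31)),
    )
    return channels, masks, coords_list, records


# ---------------------------------------------------------------------------
# cell-cycle intensities
# ---------------------------------------------------------------------------


def generate_cellcycle_intensities(
    n_cells: int, params: CellCycleSimParams | None = None, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Integrated DAPI/EdU intensities with true phase labels.

    Returns a DataFrame with linear-scale ``dapi_total`` and ``edu_total``
    plus ``true_phase`` in {G1, S, G2M, subG1, over4N}.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be > 0")
    params = params or CellCycleSimParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    u = rng.random(n_cells)
    phase = np.empty(n_cells, dtype=object)
    c1 = params.subg1_fraction
    c2 = c1 + params.over4n_fraction
    clean = 1.0 - c2
    b1 = c2 + clean * params.g1_fraction
    b2 = b1 + clean * params.s_fraction
    phase[u < c1] = "subG1"
    phase[(u >= c1) & (u < c2)] = "over4N"
    phase[(u >= c2) & (u < b1)] = "G1"
    phase[(u >= b1) & (u < b2)] = "S"
    phase[u >= b2] = "G2M"

    mu2 = params.dapi_2n_log2_mean
    mu4 = params.dapi_4n_log2_mean
    sd = params.dapi_log2_sd
    ld = np.empty(n_cells)
    for ph, gen in (
        ("G1", lambda n: rng.normal(mu2, sd, n)),
        ("G2M", lambda n: rng.normal(mu4, sd, n)),
        ("S", lambda n: rng.uniform(mu2 + 0.25, mu4 - 0.25, n)),
        ("subG1", lambda n: rng.uniform(mu2 - 1.5, mu2 - 0.6, n)),
        ("over4N", lambda n: rng.uniform(mu4 + 0.6, mu4 + 1.5, n)),
    ):
        sel = phase == ph
        ld[sel] = gen(int(sel.sum()))

    le = rng.normal(params.edu_background_log2_mean, params.edu_background_log2_sd, n_cells)
    s_sel = phase == "S"
    le[s_sel] = rng.normal(
        params.edu_background_log2_mean + params.edu_positive_log2_shift,
        0.3,
        int(s_sel.sum()),
    )
    return pd.DataFrame(
        {
            "dapi_total": np.exp2(ld),
            "edu_total": np.exp2(le),
            "true_phase": phase,
        }
    )


# ---------------------------------------------------------------------------
# whole screens (feature level)
# ---------------------------------------------------------------------------

_NULL_POOL_CACHE: dict[tuple, np.ndarray] = {}


def null_clustering_pool(
    n: int = 256,
    n_spots: int = 46,
    seed: int = 424242,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    n_mc: int = DEFAULT_N_MC,
) -> np.ndarray:
    """Empirical null distribution of per-cell clustering scores.

    Scores of ``n`` CSR patterns on a reference nucleus, produced by the
    same scorer used downstream — keeping the generator and the scorer
    self-consistent. Cached per configuration.
    """
    key = (n, n_spots, seed, round(pixel_size, 9), n_mc)
    hit = _NULL_POOL_CACHE.get(key)
    if hit is not None:
        return hit
    mask, _ = generate_nucleus_mask(NucleusShapeParams(), pixel_size, seed=0)
    rng = np.random.default_rng(seed)
    params = SpotProcessParams(n_spots=n_spots, process_kind="csr")
    scores = np.array(
        [
            clustering_score(
                sample_spots(mask, params, seed=int(rng.integers(2**31)), pixel_size=pixel_size),
                mask,
                pixel_size,
                n_mc=n_mc,
                seed=seed,
            )
            for _ in range(n)
        ]
    )
    _NULL_POOL_CACHE[key] = scores
    return scores


def _well_names(n: int) -> list[str]:
    names = []
    for r in range(16):
        for c in range(24):
            names.append(f"{chr(ord('A') + r)}{c + 1:02d}")
    return names[:n]


def build_layout(design: ScreenDesign) -> pd.DataFrame:
    """Plate layout: one row per (plate, well) with role and gene.

    Control wells are spread deterministically across each plate; library
    genes fill the remaining wells in order. The same layout applies to
    every replicate.
    """
    wells = _well_names(design.wells_per_plate)
    roles = []
    for role in CONTROL_ROLES:
        roles.extend([role] * design.control_wells_per_plate.get(role, 0))
    n_ctrl = len(roles)
    ctrl_pos = np.linspace(0, design.wells_per_plate - 1, n_ctrl).round().astype(int)
    genes = design.genes
    rows = []
    g = 0
    for plate in range(1, design.plates + 1):
        ctrl_iter = iter(roles)
        pos_set = set(ctrl_pos.tolist())
        for w_idx, well in enumerate(wells):
            if w_idx in pos_set:
                role = next(ctrl_iter)
                rows.append((plate, well, role, role))
            elif g < len(genes):
                rows.append((plate, well, "library", genes[g]))
                g += 1
    if g < len(genes):
        raise ValueError("plate count too small for the gene library")
    return pd.DataFrame(rows, columns=["plate", "well", "role", "gene"])


@dataclass
class SimulatedScreen:
    """Feature-level screen dataset with ground truth."""

    cells: pd.DataFrame
    layout: pd.DataFrame
    truth: pd.DataFrame
    null_well_sd: dict
    pool_sd: float


def generate_screen_dataset(
    design: ScreenDesign,
    level: str = "features",
    seed: int | None = None,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
) -> SimulatedScreen:
    """Generate a whole arrayed screen with known ground truth.

    At the feature level (default), per-cell rows are drawn directly:
    clustering scores come from the empirical CSR null pool shifted by the
    per-gene effect (in null well-SD units) plus a per-well random effect;
    spot counts are Poisson around the shifted baseline; per-well cell
    counts are negative-binomial, scaled by the gene's viability
    multiplier. The image level delegates to :func:`generate_image_well`
    and is intended for small smoke runs only.
    """
    if level not in ("features", "images"):
        raise ValueError("level must be 'features' or 'images'")
    seed = design.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    layout = build_layout(design)
    eff = design.resolved_effect_table()
    missing = set(layout["gene"]) - set(eff.index)
    if missing:
        raise ValueError(f"effect_table missing genes: {sorted(missing)[:5]}")

    if level == "images":
        if len(layout) * design.n_replicates > 16:
            raise ValueError(
                "image-level generation is a smoke path; restrict the design to <= 16 well-replicates"
            )

    pool = null_clustering_pool(n_spots=int(round(design.baseline_spot_count)))
    s_cell = float(pool.std(ddof=1))
    sd_well_clust = float(
        np.sqrt(
            (design.well_effect_sd * s_cell) ** 2
            + s_cell**2 / design.cells_per_well_mean
        )
    )
    lam = design.baseline_spot_count
    sd_well_count = float(
        np.sqrt(design.well_count_effect_sd**2 + lam / design.cells_per_well_mean)
    )

    # expand layout over replicates
    frames = []
    for rep in range(1, design.n_replicates + 1):
        f = layout.copy()
        f["replicate"] = rep
        frames.append(f)
    wl = pd.concat(frames, ignore_index=True)

    gene_eff = eff.loc[wl["gene"]]
    mult = gene_eff["cellnumber_multiplier"].to_numpy(float)
    mu = np.clip(design.cells_per_well_mean * mult, 0.2, None)
    k = design.cells_per_well_dispersion
    n_cells = rng.negative_binomial(k, k / (k + mu))
    well_eff_clust = rng.normal(0.0, design.well_effect_sd * s_cell, len(wl))
    well_eff_count = rng.normal(0.0, design.well_count_effect_sd, len(wl))

    total = int(n_cells.sum())
    rep_cells = np.repeat(np.arange(len(wl)), n_cells)
    shift_clust = (
        gene_eff["clustering_shift"].to_numpy(float) * sd_well_clust + well_eff_clust
    )
    clustering = pool[rng.integers(0, len(pool), total)] + shift_clust[rep_cells]
    lam_cells = np.clip(
        (lam + gene_eff["count_shift"].to_numpy(float) * sd_well_count + well_eff_count)[
            rep_cells
        ],
        0.1,
        None,
    )
    spot_count = rng.poisson(lam_cells)
    area = np.clip(rng.normal(110.0, 15.0, total), 40.0, 250.0)
    qc_rate = gene_eff["qc_fail_rate"].to_numpy(float)[rep_cells]
    fail = rng.random(total) < qc_rate
    solidity = np.where(
        fail,
        rng.uniform(0.60, 0.845, total),
        rng.uniform(0.90, 0.985, total),
    )
    radial = np.clip(rng.normal(0.66, 0.05, total), 0.0, 1.0)
    cc = generate_cellcycle_intensities(total, design.cellcycle, rng)

    cells = pd.DataFrame(
        {
            "plate": wl["plate"].to_numpy()[rep_cells],
            "well": wl["well"].to_numpy()[rep_cells],
            "replicate": wl["replicate"].to_numpy()[rep_cells],
            "role": wl["role"].to_numpy()[rep_cells],
            "gene": wl["gene"].to_numpy()[rep_cells],
            "spot_count": spot_count,
            "clustering_score": clustering,
            "radial_distance": radial,
            "nuclear_area": area,
            "solidity": solidity,
            "qc_pass": (solidity >= 0.85) & (area >= 30.0),
            "dapi_total": cc["dapi_total"].to_numpy(),
            "edu_total": cc["edu_total"].to_numpy(),
            "true_phase": cc["true_phase"].to_numpy(),
        }
    )
    truth = eff.copy()
    truth["is_effect"] = (truth["clustering_shift"] != 0) | (truth["count_shift"] != 0)
    truth["true_clustering_direction"] = np.select(
        [truth["clustering_shift"] > 0, truth["clustering_shift"] < 0],
        ["clustered", "unclustered"],
        "none",
    )
    truth["true_count_direction"] = np.select(
        [truth["count_shift"] > 0, truth["count_shift"] < 0],
        ["higher", "lower"],
        "none",
    )
    return SimulatedScreen(
        cells=cells,
        layout=layout,
        truth=truth,
        null_well_sd={"clustering": sd_well_clust, "count": sd_well_count},
        pool_sd=s_cell,
    )
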