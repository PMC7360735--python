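"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the study's data types:

* stained-smear images — elliptical cells whose pixels mix a "blue"
  hematoxylin-like dye (hue ~250 deg) with a "purple" PAS-like dye
  (hue ~270 deg) under smooth inhomogeneous illumination, with paired
  open-/blocked-light-path calibration frames and a label mask; dye hues
  follow right-skewed (exponentially modified Gaussian) distributions,
  the shape stained-smear hue histograms empirically show;
* subject-level enzyme-activity tables with linear age trends and
  multiplicative noise;
* gene-by-cell count matrices with planted myeloid/lymphoid priming and a
  proliferation-gene effect confined to old myeloid-primed cells.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage import draw as skdraw
from skimage.color import hsv2rgb

from .images import IlluminationPair

__all__ = [
    "CellSpec",
    "ImageScene",
    "CohortSpec",
    "ActivitySimSpec",
    "ExpressionSimSpec",
    "SceneRender",
    "render_scene",
    "make_grid_scene",
    "simulate_cohort_images",
    "simulate_activity_table",
    "simulate_expression_matrix",
]


# ---------------------------------------------------------------------------
# Image scenes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellSpec:
    """One elliptical cell: center (row, col), semi-axes in pixels,
    orientation in degrees, and the probability ``p_pas`` that a pixel
    carries the PAS dye rather than hematoxylin."""

    center: tuple[float, float]
    axes: tuple[float, float]
    orientation: float = 0.0
    p_pas: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_pas <= 1.0:
            raise ValueError(f"p_pas must be in [0, 1], got {self.p_pas}")
        if min(self.axes) <= 0:
            raise ValueError("ellipse semi-axes must be positive")


@dataclass
class ImageScene:
    """Full specification of one synthetic smear image.

    Dye colors are right-skewed hue distributions — Gaussian core
    ``hue_sigma`` plus exponential tail ``hue_tau`` toward larger hue, the
    exponentially-modified-Gaussian shape that stained-smear hue histograms
    show — at fixed saturation/brightness.  The illumination field is a
    per-channel 2nd-order polynomial gain rescaled into ``gain_range``;
    sensor noise is additive Gaussian on the 8-bit scale, with quantization
    half-away-from-zero.  Samples are truncated at 3 ``hue_sigma`` / 5
    ``hue_tau`` so every dye hue lies within a bounded window around its
    location.
    """

    shape: tuple[int, int] = (256, 256)
    cells: list[CellSpec] = field(default_factory=list)
    hue_hematoxylin: float = 250.0
    hue_pas: float = 270.0
    hue_sigma: float = 4.0
    hue_tau: float = 3.0
    cell_saturation: float = 0.55
    cell_brightness: float = 0.60
    background_saturation: float = 0.02
    background_brightness: float = 0.99
    gain_range: tuple[float, float] = (0.6, 0.95)
    noise_sd: float = 2.0
    dark_level: float = 8.0
    flat_illumination: bool = False
    allow_overlap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for hue in (self.hue_hematoxylin, self.hue_pas):
            if not 0.0 <= hue < 360.0:
                raise ValueError(f"dye hue must be in [0, 360), got {hue}")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.dark_level + self.gain_range[1] * 255.0 > 255.0:
            raise ValueError(
                "dark_level + max gain * 255 exceeds the 8-bit range: the "
                "open light path would saturate the sensor and flat-field "
                "correction could not be exact"
            )
        for c in self.cells:
            r, col = c.center
            a, b = max(c.axes), max(c.axes)
            if not (a <= r <= self.shape[0] - 1 - a and b <= col <= self.shape[1] - 1 - b):
                raise ValueError(f"cell at {c.center} does not fit within the canvas")


@dataclass
class SceneRender:
    """Rendered scene: 8-bit specimen, float calibration pair (modeled as
    averages of many frames, hence unquantized), label mask, the noise-free
    ideal scene, and the per-cell ground-truth table."""

    specimen: np.ndarray
    calibration: IlluminationPair
    mask: np.ndarray
    ideal: np.ndarray
    truth: pd.DataFrame


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def _dye_hue(rng, loc: float, sigma: float, tau: float, size: int) -> np.ndarray:
    """Right-skewed dye hue: location + truncated Gaussian core + truncated
    exponential tail toward larger hue (EMG-shaped, matching the model the
    deconvolution stage fits)."""
    core = (
        stats.truncnorm.rvs(-3.0, 3.0, loc=0.0, scale=sigma, size=size, random_state=rng)
        if sigma > 0 else np.zeros(size)
    )
    tail = np.minimum(rng.exponential(tau, size=size), 5.0 * tau) if tau > 0 else 0.0
    return loc + core + tail


def _gain_field(rng, shape: tuple[int, int], gain_range: tuple[float, float]) -> np.ndarray:
    """Per-channel 2nd-order polynomial gain, rescaled into gain_range."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    x = xx / max(w - 1, 1) - 0.5
    y = yy / max(h - 1, 1) - 0.5
    lo, hi = gain_range
    gain = np.empty((h, w, 3))
    for ch in range(3):
        c = rng.uniform(-1.0, 1.0, size=6)
        g = c[0] + c[1] * x + c[2] * y + c[3] * x**2 + c[4] * x * y + c[5] * y**2
        gmin, gmax = g.min(), g.max()
        if gmax - gmin < 1e-12:
            gain[..., ch] = 0.5 * (lo + hi)
        else:
            gain[..., ch] = lo + (hi - lo) * (g - gmin) / (gmax - gmin)
    return gain


def render_scene(scene: ImageScene) -> SceneRender:
    """Render a scene to (specimen, calibration pair, mask, ideal, truth).

    The ideal (noise-free, flat-light) image assigns each cell pixel to the
    PAS dye with probability ``p_pas`` (else hematoxylin), draws its hue from
    the dye's truncated-normal hue distribution, and converts (H, S, B) to
    RGB.  The specimen is ``dark + gain * ideal + noise`` quantized to 8 bits;
    the open-path frame is ``dark + gain * 255``.

    The truth table records, per cell, both the assignment probability
    ``p_pas`` and the realized PAS-pixel fraction actually rendered.
    """
    rng = np.random.default_rng(scene.seed)
    h, w = scene.shape

    bg = hsv2rgb(
        np.array(
            [scene.hue_hematoxylin / 360.0, scene.background_saturation,
             scene.background_brightness]
        ).reshape(1, 1, 3)
    )[0, 0] * 255.0
    ideal = np.tile(bg, (h, w, 1))
    mask = np.zeros((h, w), dtype=np.uint16)

    records = []
    for k, cell in enumerate(scene.cells, start=1):
        rr, cc = skdraw.ellipse(
            cell.center[0], cell.center[1], cell.axes[0], cell.axes[1],
            shape=(h, w), rotation=np.deg2rad(cell.orientation),
        )
        if not scene.allow_overlap and np.any(mask[rr, cc] != 0):
            raise ValueError(f"cell {k} overlaps a previously placed cell")
        n_px = len(rr)
        is_pas = rng.random(n_px) < cell.p_pas
        hues = np.empty(n_px)
        n_pas = int(is_pas.sum())
        hues[is_pas] = _dye_hue(rng, scene.hue_pas, scene.hue_sigma,
                                scene.hue_tau, n_pas)
        hues[~is_pas] = _dye_hue(rng, scene.hue_hematoxylin, scene.hue_sigma,
                                 scene.hue_tau, n_px - n_pas)
        hsv = np.stack(
            [
                (hues % 360.0) / 360.0,
                np.full(n_px, scene.cell_saturation),
                np.full(n_px, scene.cell_brightness),
            ],
            axis=-1,
        )
        ideal[rr, cc] = hsv2rgb(hsv.reshape(-1, 1, 3)).reshape(-1, 3) * 255.0
        mask[rr, cc] = k
        records.append(
            {
                "cell_id": k,
                "p_pas": cell.p_pas,
                "pas_fraction_realized": n_pas / n_px if n_px else np.nan,
                "n_pixels": n_px,
                "center_row": cell.center[0],
                "center_col": cell.center[1],
            }
        )

    if scene.flat_illumination:
        gain = np.ones((h, w, 3))
    else:
        gain = _gain_field(rng, (h, w), scene.gain_range)

    dark = np.full((h, w, 3), scene.dark_level, dtype=float)
    bright = dark + gain * 255.0
    specimen = dark + gain * ideal
    if scene.noise_sd > 0:
        specimen = specimen + rng.normal(0.0, scene.noise_sd, size=specimen.shape)
    specimen = np.clip(_round_half_away(specimen), 0, 255).astype(np.uint8)

    return SceneRender(
        specimen=specimen,
        calibration=IlluminationPair(bright=bright, dark=dark),
        mask=mask,
        ideal=ideal,
        truth=pd.DataFrame.from_records(records),
    )


def make_grid_scene(
    p_pas_values,
    shape: tuple[int, int] | None = None,
    axes: tuple[float, float] = (88.0, 70.0),
    spacing: int = 200,
    margin: int = 105,
    seed: int = 0,
    **scene_kwargs,
) -> ImageScene:
    """Lay cells out on a regular grid, one per ``p_pas`` value.

    A convenience constructor covering the common case of well-separated,
    non-overlapping cells; the canvas grows as needed to hold the grid.
    Default semi-axes give ~1.9e4 pixels per cell, matching a ~10-12 um
    cell imaged at 100x oil immersion (~0.07 um/px); the per-cell PAS-index
    fit needs pixel counts of this order for a ~0.01 statistical error.
    """
    p_pas_values = list(p_pas_values)
    n = len(p_pas_values)
    if n == 0:
        raise ValueError("need at least one p_pas value")
    ncol = int(np.ceil(np.sqrt(n)))
    nrow = int(np.ceil(n / ncol))
    need = (2 * margin + (nrow - 1) * spacing + 1, 2 * margin + (ncol - 1) * spacing + 1)
    if shape is None:
        shape = need
    cells = []
    for i, p in enumerate(p_pas_values):
        r = margin + (i // ncol) * spacing
        c = margin + (i % ncol) * spacing
        cells.append(CellSpec(center=(r, c), axes=axes, p_pas=float(p)))
    return ImageScene(shape=shape, cells=cells, seed=seed, **scene_kwargs)


# ---------------------------------------------------------------------------
# Cohort of subjects (young vs old)
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Young/old imaging cohort design.

    Defaults mirror the comparison design the pipeline targets: the old-group
    mean per-cell PAS fraction is ``fold_change`` (default 3.5) times the
    young mean, with greater dispersion among old cells, and at least 15
    analyzed cells per subject.
    """

    n_young: int = 3
    n_old: int = 3
    cells_per_subject: int = 24
    young_mean: float = 0.08
    fold_change: float = 3.5
    young_sd: float = 0.02
    old_sd: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold change must be > 0")
        if self.cells_per_subject < 1:
            raise ValueError("cells per subject must be >= 1")
        old_mean = self.young_mean * self.fold_change
        if not 0 < old_mean < 1:
            raise ValueError("old-group mean PAS fraction must lie in (0, 1)")

    @property
    def old_mean(self) -> float:
        return self.young_mean * self.fold_change


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    """Beta(a, b) with the given mean and (capped) sd."""
    max_var = mean * (1 - mean)
    var = min(sd**2, 0.95 * max_var)
    nu = max_var / var - 1.0
    return mean * nu, (1.0 - mean) * nu


@dataclass
class SubjectImages:
    subject_id: str
    group: str
    render: SceneRender


def simulate_cohort_images(spec: CohortSpec, **scene_kwargs) -> list[SubjectImages]:
    """One rendered image set per subject, per-cell truth recorded.

    Per-cell PAS fractions are Beta-distributed with group mean/SD from the
    spec, so the old/young ratio of true means equals the fold change up to
    sampling error.
    """
    rng = np.random.default_rng(spec.seed)
    out = []
    groups = [("young", spec.n_young, spec.young_mean, spec.young_sd),
              ("old", spec.n_old, spec.old_mean, spec.old_sd)]
    for group, n_sub, mean, sd in groups:
        a, b = _beta_params(mean, sd)
        for s in range(n_sub):
            p = rng.beta(a, b, size=spec.cells_per_subject)
            scene = make_grid_scene(
                p, seed=int(rng.integers(2**31 - 1)), **scene_kwargs
            )
            render = render_scene(scene)
            render.truth["subject_id"] = f"{group}_{s + 1}"
            render.truth["group"] = group
            out.append(SubjectImages(f"{group}_{s + 1}", group, render))
    return out


# ---------------------------------------------------------------------------
# Enzyme-activity tables
# ---------------------------------------------------------------------------

DEFAULT_ENZYMES = ("pk_ref", "aldolase", "adenylate_kinase", "tpi", "hexokinase")


@dataclass
class ActivitySimSpec:
    """Subject-level enzyme activities with a linear age trend and
    log-normal multiplicative noise: ``activity = (baseline + slope * age)
    * exp(N(0, noise_sd))``."""

    n_subjects: int = 9
    age_range: tuple[float, float] = (19.0, 71.0)
    baselines: dict = field(
        default_factory=lambda: {
            "pk_ref": 0.30, "aldolase": 0.20, "adenylate_kinase": 2.0,
            "tpi": 0.08, "hexokinase": 10.0,
        }
    )
    slopes: dict = field(
        default_factory=lambda: {
            "pk_ref": 0.006, "aldolase": 0.013, "adenylate_kinase": 0.19,
            "tpi": 0.002, "hexokinase": 0.05,
        }
    )
    noise_sd: float = 0.3
    reference: str = "pk_ref"
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.baselines) != set(self.slopes):
            raise ValueError("baselines and slopes must cover the same enzymes")
        if self.reference not in self.baselines:
            raise ValueError(f"reference column {self.reference!r} not among enzymes")
        for age in self.age_range:
            for enz in self.baselines:
                if self.baselines[enz] + self.slopes[enz] * age <= 0:
                    raise ValueError(
                        f"expected activity of {enz} non-positive at age {age}"
                    )


def simulate_activity_table(spec: ActivitySimSpec) -> pd.DataFrame:
    """Simulate a subject x enzyme activity table (id, age, sex, enzymes...)."""
    rng = np.random.default_rng(spec.seed)
    ages = np.sort(rng.uniform(*spec.age_range, size=spec.n_subjects))
    table = pd.DataFrame(
        {
            "id": [f"S{i + 1:03d}" for i in range(spec.n_subjects)],
            "age": ages,
            "sex": rng.choice(["f", "m"], size=spec.n_subjects),
        }
    )
    for enz in spec.baselines:
        mean = spec.baselines[enz] + spec.slopes[enz] * ages
        noise = np.exp(rng.normal(0.0, spec.noise_sd, size=spec.n_subjects))
        table[enz] = mean * noise
    return table


# ---------------------------------------------------------------------------
# Gene-by-cell count matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionSimSpec:
    """Count matrix with planted lineage priming.

    Two young and two old donors by default, each contributing
    ``cells_per_group`` myeloid-primed and lymphoid-primed cells.  Marker
    genes of a cell's own lineage are elevated ``marker_effect``-fold;
    proliferation genes are elevated ``proliferation_effect``-fold only in
    old myeloid-primed cells.  Counts are negative binomial with dispersion
    ``dispersion`` (Poisson when 0).

    Proliferation genes get their own sparse baseline
    (``proliferation_baseline_mean``) so that detection — expressed in a
    minimum fraction of a group's cells — separates the boosted old
    myeloid-primed group from the others instead of saturating everywhere.
    """

    n_genes: int = 200
    n_markers: int = 8
    n_proliferation: int = 10
    donors: tuple = (("Y1", "young"), ("Y2", "young"), ("O1", "old"), ("O2", "old"))
    cells_per_group: int = 30
    baseline_mean: float = 2.0
    proliferation_baseline_mean: float = 0.2
    marker_effect: float = 10.0
    proliferation_effect: float = 3.0
    dispersion: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.marker_effect < 1 or self.proliferation_effect < 1:
            raise ValueError("effect multipliers must be >= 1")
        needed = 2 * self.n_markers + self.n_proliferation
        if self.n_genes < needed:
            raise ValueError(f"need at least {needed} genes for the marker sets")

    @property
    def myeloid_markers(self) -> list[str]:
        return [f"MYE{i + 1}" for i in range(self.n_markers)]

    @property
    def lymphoid_markers(self) -> list[str]:
        return [f"LYM{i + 1}" for i in range(self.n_markers)]

    @property
    def proliferation_genes(self) -> list[str]:
        return [f"PRO{i + 1}" for i in range(self.n_proliferation)]

    @property
    def gene_names(self) -> list[str]:
        special = self.myeloid_markers + self.lymphoid_markers + self.proliferation_genes
        n_bg = self.n_genes - len(special)
        return special + [f"G{i + 1:04d}" for i in range(n_bg)]


def _nb_sample(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_expression_matrix(
    spec: ExpressionSimSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate (genes x cells count matrix, true per-cell annotations)."""
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_names
    mye = set(spec.myeloid_markers)
    lym = set(spec.lymphoid_markers)
    pro = set(spec.proliferation_genes)

    columns, ann = [], []
    data = []
    for donor, age_group in spec.donors:
        for lineage in ("myeloid", "lymphoid"):
            for i in range(spec.cells_per_group):
                cell_id = f"{donor}_{lineage[:3]}_{i + 1}"
                mean = np.full(len(genes), spec.baseline_mean)
                own = mye if lineage == "myeloid" else lym
                for g_idx, g in enumerate(genes):
                    if g in pro:
                        mean[g_idx] = spec.proliferation_baseline_mean
                        if age_group == "old" and lineage == "myeloid":
                            mean[g_idx] *= spec.proliferation_effect
                    elif g in own:
                        mean[g_idx] *= spec.marker_effect
                data.append(_nb_sample(rng, mean, spec.dispersion))
                columns.append(cell_id)
                ann.append(
                    {
                        "cell_id": cell_id,
                        "donor": donor,
                        "age_group": age_group,
                        "lineage": lineage,
                    }
                )
    matrix = pd.DataFrame(
        np.array(data).T, index=pd.Index(genes, name="gene"), columns=columns
    )
    return matrix, pd.DataFrame(ann).set_index("cell_id")
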