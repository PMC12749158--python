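"""Formula-defined quantitative phenotype readouts.

Implements the single-cell and plate-level assay quantifications used to
validate the transcriptome predictions: cell shape and calcium-induced
contraction, DAPI-integral cell-cycle gating and BrdU positivity, neutral
lipid scores, mito-stress-test OCR parameters, random motility from nucleus
tracks, glucose/lactate fluxes, caspase activity rate, and the
nuclear/perinuclear fluorescence ratio.

Segmented objects arrive as tables (one row per cell/nucleus) with the
documented columns; no image processing happens here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: single-cell filter bounds for the contractility assay (area in um^2)
CELL_AREA_MIN = 400.0
CELL_AREA_MAX = 4000.0

OCR_PHASES = ("baseline", "oligomycin", "fccp", "rot_aa")


# ---------------------------------------------------------------------------
# shape / contraction
# ---------------------------------------------------------------------------

def circularity(area, perimeter, clip: bool = True):
    """Circularity C = 4*pi*A/P^2; 1 for a circle, -> 0 for elongated shapes.

    Values marginally above 1 (discretized perimeters) are clipped to 1 with
    a warning.  Accepts scalars or arrays.
    """
    area = np.asarray(area, dtype=float)
    perimeter = np.asarray(perimeter, dtype=float)
    if (area <= 0).any() or (perimeter <= 0).any():
        raise ValueError("area and perimeter must be positive")
    c = 4.0 * np.pi * area / perimeter**2
    if clip and (c > 1.0).any():
        warnings.warn("circularity > 1 clipped to 1 (segmentation noise)", stacklevel=2)
        c = np.minimum(c, 1.0)
    return float(c) if c.ndim == 0 else c


def ellipse_perimeter(a: float, b: float) -> float:
    """Ramanujan's approximation to the perimeter of an ellipse."""
    a, b = float(a), float(b)
    return np.pi * (3.0 * (a + b) - np.sqrt((3.0 * a + b) * (a + 3.0 * b)))


def ellipse_circularity(aspect_ratio: float) -> float:
    """Circularity of an ellipse with the given major/minor axis ratio."""
    r = float(aspect_ratio)
    if r < 1.0:
        r = 1.0 / r
    area = np.pi * r  # semi-axes (r, 1)
    return 4.0 * np.pi * area / ellipse_perimeter(r, 1.0) ** 2


def aspect_ratio_for_circularity(target: float) -> float:
    """Invert `ellipse_circularity`: the axis ratio giving a target C."""
    if not 0.0 < target <= 1.0:
        raise ValueError("target circularity must be in (0, 1]")
    if target == 1.0:
        return 1.0
    return float(brentq(lambda r: ellipse_circularity(r) - target, 1.0 + 1e-9, 1e4))


def filter_cells(objects: pd.DataFrame) -> pd.DataFrame:
    """Keep single-nucleus objects with area in [400, 4000] um^2.

    Removes segmentation artefacts (small fragments) and cell clumps.
    """
    keep = (
        (objects["n_nuclei"] == 1)
        & (objects["area_um2"] >= CELL_AREA_MIN)
        & (objects["area_um2"] <= CELL_AREA_MAX)
    )
    return objects.loc[keep].copy()


def contractility_assay(
    before: pd.DataFrame, after: pd.DataFrame
) -> tuple[float, float, float]:
    """Median circularity before/after ionophore and the contraction index.

    Circularity is not normally distributed, so the per-sample median is the
    summary statistic.  contraction_index = (median_after - median_before) /
    median_before; a positive value indicates contraction (rounding up).
    Inputs are expected pre-filtered (see `filter_cells`).
    """
    if before.empty or after.empty:
        raise ValueError("empty cell-object table")
    med_before = float(np.median(circularity(before["area_um2"], before["perimeter_um"])))
    med_after = float(np.median(circularity(after["area_um2"], after["perimeter_um"])))
    return med_before, med_after, (med_after - med_before) / med_before


CONTRACTION_MODES = ("area_conserving_2d", "volume_conserving_3d", "width_constant")


def contraction_model(
    aspect_ratio: float,
    shortening_fraction: float,
    mode: str = "volume_conserving_3d",
) -> tuple[float, float]:
    """Predicted circularity change of an ellipsoidal cell that shortens.

    The cell footprint is an ellipse with axes (a, b), a/b = aspect_ratio.
    Contraction shortens the long axis by ``shortening_fraction`` (s); the
    short axis responds per ``mode``:

    - ``area_conserving_2d``: footprint area conserved, b' = b/(1-s)
    - ``volume_conserving_3d``: prolate ellipsoid volume (~ a*b^2) conserved
      with isotropic widening, b' = b/sqrt(1-s)
    - ``width_constant``: b unchanged

    Returns (circularity_before, circularity_after).  If shortening pushes
    the ratio below 1 the axes are swapped (the cell is now longer across).
    """
    r = float(aspect_ratio)
    s = float(shortening_fraction)
    if r < 1.0:
        raise ValueError("aspect_ratio must be >= 1")
    if not 0.0 <= s < 1.0:
        raise ValueError("shortening_fraction must be in [0, 1)")
    if mode not in CONTRACTION_MODES:
        raise ValueError(f"mode must be one of {CONTRACTION_MODES}")
    circ_before = ellipse_circularity(r)
    a, b = r, 1.0
    a2 = a * (1.0 - s)
    if mode == "area_conserving_2d":
        b2 = b / (1.0 - s)
    elif mode == "volume_conserving_3d":
        b2 = b / np.sqrt(1.0 - s)
    else:
        b2 = b
    ratio2 = a2 / b2
    circ_after = ellipse_circularity(ratio2)  # axis swap handled inside
    return circ_before, circ_after


# ---------------------------------------------------------------------------
# cell cycle / DNA synthesis
# ---------------------------------------------------------------------------

@dataclass
class CycleGates:
    """DAPI-integral gates and the resulting G1/S/G2 fractions."""

    g1_mode: float
    boundaries: tuple[float, float, float, float]  # g1_lo, g1_hi(=s_lo), s_hi(=g2_lo), g2_hi
    fractions: tuple[float, float, float]
    n_gated: int
    n_excluded: int

    def __post_init__(self) -> None:
        b = self.boundaries
        if not (b[0] < b[1] < b[2] < b[3]):
            raise ValueError("gate boundaries must be strictly increasing")


def gate_cell_cycle(dapi_integrals, window: float = 0.3) -> CycleGates:
    """Gate nuclei into G1/S/G2 from the DAPI-integral distribution.

    The DAPI integral (nuclear area x mean DAPI fluorescence) is a relative
    DNA-content proxy: G1 nuclei cluster at a mode m, G2 nuclei at 2m, S in
    between.  m is located as the kernel-density maximum over the lower half
    of the distribution; gates are m*(1 +/- window/2) for G1 and
    2m*(1 +/- window/2) for G2, with S bridging them.  Nuclei outside the
    outer bounds are excluded as debris/aggregates.
    """
    x = np.asarray(dapi_integrals, dtype=float)
    x = x[np.isfinite(x) & (x > 0)]
    if len(x) == 0:
        raise ValueError("no usable DAPI integrals")
    if len(x) < 100:
        warnings.warn(
            f"only {len(x)} nuclei; cell-cycle gating is unreliable below ~100",
            stacklevel=2,
        )
    lower = x[x <= np.median(x)]
    if len(np.unique(lower)) == 1:
        m = float(lower[0])
    else:
        kde = sps.gaussian_kde(lower)
        grid = np.linspace(lower.min(), lower.max(), 512)
        m = float(grid[np.argmax(kde(grid))])
    half = window / 2.0
    g1_lo, g1_hi = m * (1 - half), m * (1 + half)
    g2_lo, g2_hi = 2 * m * (1 - half), 2 * m * (1 + half)
    gated = (x >= g1_lo) & (x <= g2_hi)
    xg = x[gated]
    n_gated = int(len(xg))
    if n_gated == 0:
        raise ValueError("no nuclei inside the cycle gates")
    g1 = (xg <= g1_hi).sum()
    g2 = (xg >= g2_lo).sum()
    s = n_gated - g1 - g2
    return CycleGates(
        g1_mode=m,
        boundaries=(g1_lo, g1_hi, g2_lo, g2_hi),
        fractions=(g1 / n_gated, s / n_gated, g2 / n_gated),
        n_gated=n_gated,
        n_excluded=int(len(x) - n_gated),
    )


def brdu_call(
    nuclear_red_integrals,
    negative_control_integrals,
    quantile: float = 0.99,
    method: str = "quantile",
) -> tuple[float, float]:
    """BrdU positivity against a negative-control-derived threshold.

    ``method='quantile'`` (default) takes the stated quantile of the
    negative-control red integrals; ``method='mean_sd'`` uses mean + 3*SD.
    Returns (threshold, positive_fraction).
    """
    sample = np.asarray(nuclear_red_integrals, dtype=float)
    control = np.asarray(negative_control_integrals, dtype=float)
    if sample.size == 0 or control.size == 0:
        raise ValueError("empty sample or negative control")
    if method == "quantile":
        thr = float(np.quantile(control, quantile))
    elif method == "mean_sd":
        thr = float(control.mean() + 3.0 * control.std(ddof=1))
    else:
        raise ValueError("method must be 'quantile' or 'mean_sd'")
    return thr, float((sample > thr).mean())


# ---------------------------------------------------------------------------
# lipid accumulation
# ---------------------------------------------------------------------------

def lipid_score(
    red_objects: pd.DataFrame,
    n_nuclei: int,
    intensity_col: str = "ch_red_mean",
    area_col: str = "area_um2",
) -> float:
    """Per-well neutral lipid score.

    (mean red intensity of red objects) x (mean red-object area) x
    (red-object count) / (nucleus count).  Zero when no red objects.
    """
    if n_nuclei <= 0:
        raise ValueError("n_nuclei must be positive")
    if red_objects.empty:
        return 0.0
    mean_int = float(red_objects[intensity_col].mean())
    mean_area = float(red_objects[area_col].mean())
    return mean_int * mean_area * len(red_objects) / float(n_nuclei)


def lipid_compartments(
    red_objects: pd.DataFrame,
    nuclei: pd.DataFrame,
    perinuclear_radius: float = 5.0,
    intensity_col: str = "ch_red_mean",
    area_col: str = "area_um2",
) -> tuple[float, float]:
    """Split the lipid score into perinuclear and peripheral components.

    A red object is perinuclear when its centroid lies within
    ``perinuclear_radius`` um of the nearest nucleus boundary, proxied by the
    nucleus centroid plus its equivalent radius sqrt(area/pi).
    Returns (perinuclear_score, peripheral_score).
    """
    if nuclei.empty:
        raise ValueError("empty nuclei table")
    n_nuclei = len(nuclei)
    if red_objects.empty:
        return 0.0, 0.0
    tree = cKDTree(nuclei[["x_um", "y_um"]].to_numpy(dtype=float))
    dist, idx = tree.query(red_objects[["x_um", "y_um"]].to_numpy(dtype=float))
    r_eq = np.sqrt(nuclei[area_col].to_numpy(dtype=float)[idx] / np.pi)
    peri = dist <= (r_eq + perinuclear_radius)
    peri_score = (
        lipid_score(red_objects.loc[peri], n_nuclei, intensity_col, area_col)
        if peri.any()
        else 0.0
    )
    periph_score = (
        lipid_score(red_objects.loc[~peri], n_nuclei, intensity_col, area_col)
        if (~peri).any()
        else 0.0
    )
    return peri_score, periph_score


# ---------------------------------------------------------------------------
# mitochondrial respiration (mito stress test)
# ---------------------------------------------------------------------------

@dataclass
class OCRParams:
    """Derived mito-stress-test quantities (all rates in pmol O2/min).

    The test injects oligomycin (blocks ATP synthase), FCCP (uncouples) and
    rotenone/antimycin A (blocks complexes I/III) in sequence.  Derived:
    nmoc = non-mitochondrial OCR (rot/AA minimum); br = basal mitochondrial
    respiration; pl = proton leak; atp_ocr = ATP-synthesis-linked OCR
    (br - pl); max_ocr = FCCP maximum minus nmoc.  Two coupling-efficiency
    conventions are reported side by side: ``coupling_methods`` =
    ((br+nmoc)-(pl+nmoc))/(br+nmoc) (i.e. relative to total basal OCR) and
    ``coupling_results`` = atp_ocr/br (relative to mitochondrial basal OCR);
    ``utilization`` = br/max_ocr.
    """

    ocr_baseline: float
    ocr_oligo_min: float
    ocr_fccp_max: float
    ocr_rotaa_min: float
    nmoc: float
    br: float
    pl: float
    atp_ocr: float
    max_ocr: float
    max_ocr_raw: float
    coupling_methods: float
    coupling_results: float
    utilization: float
    flags: tuple[str, ...] = field(default_factory=tuple)


def ocr_params(trace: pd.DataFrame) -> OCRParams:
    """Derive mito-stress-test parameters from a phase-annotated OCR trace.

    ``trace`` needs columns ``time_min``, ``ocr``, ``phase`` with phases in
    {baseline, oligomycin, fccp, rot_aa}; every phase must have at least one
    measurement.  Baseline OCR is the mean of the baseline phase; the
    oligomycin and rotenone/antimycin responses are phase minima and the
    FCCP response the phase maximum.
    """
    missing = [p for p in OCR_PHASES if p not in set(trace["phase"])]
    if missing:
        raise ValueError(f"OCR trace missing phase(s): {missing}")
    by = {p: trace.loc[trace["phase"] == p, "ocr"].to_numpy(dtype=float) for p in OCR_PHASES}
    baseline = float(by["baseline"].mean())
    oligo_min = float(by["oligomycin"].min())
    fccp_max = float(by["fccp"].max())
    rotaa_min = float(by["rot_aa"].min())

    nmoc = rotaa_min
    br = baseline - nmoc
    pl = oligo_min - nmoc
    atp = br - pl
    max_raw = fccp_max
    max_corr = fccp_max - nmoc

    flags: list[str] = []
    if br <= 0:
        flags.append("nonpositive_basal_respiration")
    if pl < 0:
        flags.append("negative_proton_leak")
    if pl > br > 0:
        flags.append("proton_leak_exceeds_basal")
    if max_corr <= 0:
        flags.append("nonpositive_max_ocr")

    total_basal = br + nmoc
    coupling_methods = ((br + nmoc) - (pl + nmoc)) / total_basal if total_basal > 0 else np.nan
    coupling_results = atp / br if br > 0 else np.nan
    utilization = br / max_corr if max_corr > 0 else np.nan
    return OCRParams(
        ocr_baseline=baseline,
        ocr_oligo_min=oligo_min,
        ocr_fccp_max=fccp_max,
        ocr_rotaa_min=rotaa_min,
        nmoc=nmoc,
        br=br,
        pl=pl,
        atp_ocr=atp,
        max_ocr=max_corr,
        max_ocr_raw=max_raw,
        coupling_methods=float(coupling_methods),
        coupling_results=float(coupling_results),
        utilization=float(utilization),
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# random motility
# ---------------------------------------------------------------------------

@dataclass
class Track:
    """Time-ordered positions of one tracked nucleus."""

    nucleus_id: int
    times: np.ndarray  # h
    xs: np.ndarray  # um
    ys: np.ndarray  # um

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xs = np.asarray(self.xs, dtype=float)
        self.ys = np.asarray(self.ys, dtype=float)
        if len(self.times) < 2:
            raise ValueError("a track needs at least 2 positions")
        if not (np.diff(self.times) > 0).all():
            raise ValueError("track times must be strictly increasing")


def link_tracks(frames: pd.DataFrame, max_step: float) -> list[Track]:
    """Link nuclei across frames by greedy mutual nearest neighbours.

    ``frames`` has columns ``time_h``, ``x_um``, ``y_um``.  Between
    consecutive frames, pairs that are each other's nearest neighbour and
    closer than ``max_step`` are linked; everything else starts or ends a
    track.  Only tracks with >= 2 positions are returned.
    """
    times = sorted(frames["time_h"].unique())
    if len(times) < 2:
        raise ValueError("need at least 2 frames")
    per_frame = []
    for t in times:
        sub = frames.loc[frames["time_h"] == t, ["x_um", "y_um"]].to_numpy(dtype=float)
        if len(sub) == 0:
            raise ValueError(f"empty frame at t={t}")
        per_frame.append(sub)

    # paths: list of [(t, x, y), ...]; active maps point-index-in-last-frame -> path
    paths: list[list[tuple[float, float, float]]] = []
    active: dict[int, int] = {}
    for i, (x, y) in enumerate(per_frame[0]):
        paths.append([(times[0], x, y)])
        active[i] = i
    for fi in range(1, len(times)):
        prev, curr = per_frame[fi - 1], per_frame[fi]
        d = np.linalg.norm(prev[:, None, :] - curr[None, :, :], axis=2)
        nn_prev = d.argmin(axis=1)  # for each prev point, closest curr
        nn_curr = d.argmin(axis=0)  # for each curr point, closest prev
        new_active: dict[int, int] = {}
        for j in range(len(curr)):
            i = nn_curr[j]
            if nn_prev[i] == j and d[i, j] <= max_step and i in active:
                pid = active[i]
                paths[pid].append((times[fi], curr[j, 0], curr[j, 1]))
                new_active[j] = pid
            else:
                paths.append([(times[fi], curr[j, 0], curr[j, 1])])
                new_active[j] = len(paths) - 1
        active = new_active

    tracks = []
    nid = 0
    for path in paths:
        if len(path) < 2:
            continue
        arr = np.asarray(path)
        tracks.append(Track(nucleus_id=nid, times=arr[:, 0], xs=arr[:, 1], ys=arr[:, 2]))
        nid += 1
    return tracks


def displacement_rate(track: Track, t_start: float, t_end: float) -> float:
    """Net displacement rate sqrt(dx^2 + dy^2)/(t_end - t_start) in um/h.

    Net, not path length: a closed loop scores 0.
    """
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    rate_positions = {}
    for t in (t_start, t_end):
        match = np.isclose(track.times, t)
        if not match.any():
            raise ValueError(f"track has no position at t={t}")
        i = int(np.argmax(match))
        rate_positions[t] = (track.xs[i], track.ys[i])
    (x0, y0), (x1, y1) = rate_positions[t_start], rate_positions[t_end]
    return float(np.hypot(x1 - x0, y1 - y0) / (t_end - t_start))


# ---------------------------------------------------------------------------
# plate assays
# ---------------------------------------------------------------------------

def metabolic_fluxes(
    glu_no_cells: float,
    glu_treated: float,
    lac_no_cells: float,
    lac_treated: float,
    protein: float,
) -> tuple[float, float, float]:
    """Glucose consumption, lactate production (per mg protein) and the
    glycolytic index = produced lactate / (2 x consumed glucose).

    The index is 1 when all consumed glucose leaves as lactate (fully
    glycolytic disposal); NaN (flagged) when consumption is non-positive.
    """
    if protein <= 0:
        raise ValueError("protein amount must be positive")
    consumption = (glu_no_cells - glu_treated) / protein
    production = (lac_treated - lac_no_cells) / protein
    if consumption <= 0:
        logger.warning("non-positive glucose consumption; glycolytic index undefined")
        index = float("nan")
    else:
        index = production / (2.0 * consumption)
    return consumption, production, index


def normalized_rate(
    f_t1: float, f_t2: float, t1: float, t2: float, protein: float
) -> float:
    """Protein-normalized signal slope, e.g. caspase-3 activity between the
    30 and 60 min reads: (f_t2 - f_t1)/(t2 - t1)/protein."""
    if t2 <= t1:
        raise ValueError("t2 must exceed t1")
    if protein <= 0:
        raise ValueError("protein amount must be positive")
    return (f_t2 - f_t1) / (t2 - t1) / protein


def nuclear_perinuclear_ratio(
    nuclear_mean: float, ring_mean: float, background: float
) -> float:
    """Background-subtracted nuclear over perinuclear-ring mean fluorescence.

    The ring is a 5 um-wide annulus around the nucleus; a ratio > 1 means
    nuclear accumulation of the stained protein.  NaN (flagged) when the ring
    signal does not exceed background.
    """
    if ring_mean <= background:
        logger.warning("ring fluorescence at/below background; ratio undefined")
        return float("nan")
    return (nuclear_mean - background) / (ring_mean - background)
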