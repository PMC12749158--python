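"""Seeded synthetic data with the statistical structure the analysis assumes.

The count simulator emulates the study design: each animal contributes a
strictly connected four-condition sample quadruple (CTRL, MET, HUM, ALL),
counts are negative-binomial with lognormal animal random effects, and the
per-gene log2 mean under the combined condition is
baseline + animal + beta_met + beta_hum + gamma, where gamma is the
interaction (synergy) term.  Cell-type profiles encode the study's
qualitative contrast as generative truth: the wildtype smooth-muscle
profile has humoral effects and a nonzero interaction; the EGFR-knockout
and endothelial profiles have neither.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CONDITIONS, CountMatrix, SampleSheet
from .phenotypes import OCR_PHASES, contraction_model, ellipse_perimeter

TRUE_CLASSES = ("null", "metabolic", "humoral", "additive", "synergistic")

#: profiles without a humoral main effect or a metabolic-humoral interaction
NO_SYNERGY_PROFILES = ("KO_VSMC", "EC")


@dataclass
class SimConfig:
    """Count-simulation settings; defaults emulate the study conditions.

    Four animals per cell type, ~10k expressed genes, negative-binomial
    dispersion 0.05 and an animal effect of 0.1 log2 units give an average
    control CV near 0.21-0.24, so the derived 3xCV fold-change threshold
    lands near the 0.64-0.7 range the design targets.  Effect sizes of one
    log2 unit represent clear two-fold regulation.
    """

    n_genes: int = 10_000
    n_animals: int = 4
    cell_profile: str = "WT_VSMC"
    sex: str = "male"
    frac_met: float = 0.15
    frac_hum: float = 0.10
    frac_synergy: float = 0.20
    effect_size_log2: float = 1.0
    interaction_log2: float = 1.0
    animal_sd_log2: float = 0.1
    dispersion: float = 0.05
    lib_size_mean: int = 5_000_000
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.frac_met, self.frac_hum, self.frac_synergy)
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("effect fractions must be in [0, 1]")
        if sum(fracs) > 1.0 + 1e-12:
            raise ValueError("effect fractions must sum to at most 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.n_genes < 1 or self.n_animals < 2:
            raise ValueError("need at least 1 gene and 2 animals")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson: var = mu + dispersion*mu^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, SampleSheet, pd.DataFrame]:
    """Simulate a paired-design count matrix with known per-gene truth.

    Returns (counts, sample sheet, truth table).  The truth table is indexed
    by gene with the generative class and the true per-condition log2
    effects (``log2fc_met``, ``log2fc_hum``, ``log2fc_all``).
    """
    rng = np.random.default_rng(config.seed)
    ng, na = config.n_genes, config.n_animals
    genes = [f"gene{g:05d}" for g in range(ng)]

    n_met = int(round(config.frac_met * ng))
    n_hum = int(round(config.frac_hum * ng))
    n_syn = int(round(config.frac_synergy * ng))
    classes = np.array(["null"] * ng, dtype=object)
    order = rng.permutation(ng)
    classes[order[:n_met]] = "metabolic"
    classes[order[n_met:n_met + n_hum]] = "humoral"
    classes[order[n_met + n_hum:n_met + n_hum + n_syn]] = "synergistic"

    sign = rng.choice([-1.0, 1.0], size=ng)
    beta_met = np.where(classes == "metabolic", sign * config.effect_size_log2, 0.0)
    beta_hum = np.where(classes == "humoral", sign * config.effect_size_log2, 0.0)
    gamma = np.where(classes == "synergistic", sign * config.interaction_log2, 0.0)
    if config.cell_profile in NO_SYNERGY_PROFILES:
        beta_hum = np.zeros(ng)
        gamma = np.zeros(ng)
        classes = np.where(np.isin(classes, ["humoral", "synergistic"]), "null", classes)

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=ng)
    animal_eff = rng.normal(0.0, config.animal_sd_log2, size=(ng, na))

    x = {"CTRL": (0, 0), "MET": (1, 0), "HUM": (0, 1), "ALL": (1, 1)}
    sample_ids, rows, cols = [], [], []
    for a in range(na):
        animal = f"animal{a + 1}"
        for cond in CONDITIONS:
            xm, xh = x[cond]
            log2mu = (
                baseline
                + animal_eff[:, a]
                + xm * beta_met
                + xh * beta_hum
                + xm * xh * gamma
            )
            rel = 2.0 ** log2mu
            mu = rel / rel.sum() * config.lib_size_mean
            counts = _nb_draw(rng, mu, config.dispersion)
            sid = f"{animal}_{cond}"
            sample_ids.append(sid)
            cols.append(counts)
            rows.append(
                {
                    "sample_id": sid,
                    "animal_id": animal,
                    "cell_type": config.cell_profile,
                    "sex": config.sex,
                    "passage": 3,
                    "condition": cond,
                }
            )
    matrix = CountMatrix(genes, sample_ids, np.column_stack(cols))
    sheet = SampleSheet(pd.DataFrame(rows))
    truth = pd.DataFrame(
        {
            "true_class": classes,
            "log2fc_met": beta_met,
            "log2fc_hum": beta_hum,
            "log2fc_all": beta_met + beta_hum + gamma,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return matrix, sheet, truth


def simulate_cell_objects(
    n_cells: int,
    aspect_ratio_mean: float = 9.0,
    aspect_ratio_sd: float = 2.0,
    contraction_factor: float = 0.2,
    mode: str = "volume_conserving_3d",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired before/after cell-object tables for the contractility assay.

    Cells are ellipses with lognormal areas spanning the 400-4000 um^2
    filter window (some outside it) and occasional two-nucleus clumps to
    exercise the object filter.  The "after" table applies the contraction
    model forward operator at ``contraction_factor`` shortening.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    rng = np.random.default_rng(seed)
    ratios = np.maximum(rng.normal(aspect_ratio_mean, aspect_ratio_sd, n_cells), 1.0)
    areas = rng.lognormal(np.log(1400.0), 0.7, n_cells)
    n_nuclei = rng.choice([1, 2], size=n_cells, p=[0.9, 0.1])
    xs = rng.uniform(0, 1000, n_cells)
    ys = rng.uniform(0, 1000, n_cells)

    # semi-axes from area and ratio: A = pi*a*b, a = r*b
    b = np.sqrt(areas / (np.pi * ratios))
    a = ratios * b

    def table(a_arr: np.ndarray, b_arr: np.ndarray) -> pd.DataFrame:
        per = np.array([ellipse_perimeter(ai, bi) for ai, bi in zip(a_arr, b_arr)])
        return pd.DataFrame(
            {
                "object_id": np.arange(n_cells),
                "area_um2": np.pi * a_arr * b_arr,
                "perimeter_um": per,
                "n_nuclei": n_nuclei,
                "x_um": xs,
                "y_um": ys,
            }
        )

    s = float(contraction_factor)
    a2 = a * (1.0 - s)
    if mode == "area_conserving_2d":
        b2 = b / (1.0 - s)
    elif mode == "volume_conserving_3d":
        b2 = b / np.sqrt(1.0 - s)
    elif mode == "width_constant":
        b2 = b.copy()
    else:
        raise ValueError(f"unknown contraction mode: {mode}")
    swap = a2 < b2
    a2[swap], b2[swap] = b2[swap], a2[swap]
    return table(a, b), table(a2, b2)


def simulate_dapi(
    n_nuclei: int,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    g1_mode: float = 1000.0,
    cv: float = 0.05,
    s_range: tuple[float, float] = (1.15, 1.7),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """DAPI-integral mixture with known G1/S/G2 membership.

    G1 lognormal at the mode, G2 lognormal at twice the mode, S a uniform
    bridge over ``s_range`` (in units of the G1 mode).  The default bridge
    spans the region between the G1 and G2 gates at the default +/-15%
    gating window, so truth labels are recoverable by the gating procedure.
    Returns (integrals, labels) with labels in {'G1','S','G2'}.  cv=0
    degenerates to exact spikes.
    """
    f = np.asarray(fractions, dtype=float)
    if f.min() < 0 or not np.isclose(f.sum(), 1.0):
        raise ValueError("fractions must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    labels = rng.choice(["G1", "S", "G2"], size=n_nuclei, p=f)
    sigma = np.sqrt(np.log1p(cv**2))
    out = np.empty(n_nuclei)
    g1 = labels == "G1"
    g2 = labels == "G2"
    s = labels == "S"
    if sigma == 0:
        out[g1] = g1_mode
        out[g2] = 2 * g1_mode
    else:
        out[g1] = g1_mode * rng.lognormal(0.0, sigma, g1.sum())
        out[g2] = 2 * g1_mode * rng.lognormal(0.0, sigma, g2.sum())
    out[s] = rng.uniform(s_range[0] * g1_mode, s_range[1] * g1_mode, s.sum())
    return out, labels


def simulate_ocr_trace(
    br: float,
    pl: float,
    nmoc: float,
    max_ocr: float,
    noise_sd: float = 0.0,
    n_per_phase: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Phase-structured mito-stress-test trace whose derived parameters
    recover the inputs (exactly at noise 0).

    ``max_ocr`` is the NMOC-corrected maximal respiration; phase plateau
    levels are baseline = br + nmoc, oligomycin = pl + nmoc,
    fccp = max_ocr + nmoc, rot_aa = nmoc.
    """
    if min(br, pl, nmoc, max_ocr) < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    levels = {
        "baseline": br + nmoc,
        "oligomycin": pl + nmoc,
        "fccp": max_ocr + nmoc,
        "rot_aa": nmoc,
    }
    rows = []
    t = 0.0
    for phase in OCR_PHASES:
        for _ in range(n_per_phase):
            ocr = levels[phase] + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append({"time_min": t, "ocr": ocr, "phase": phase})
            t += 6.5
    return pd.DataFrame(rows)


def simulate_tracks(
    n_nuclei: int,
    speed_um_h: float,
    n_frames: int = 3,
    dt_h: float = 2.5,
    field_um: float = 1000.0,
    seed: int = 0,
    directed: bool = False,
) -> pd.DataFrame:
    """Nucleus positions over time as a frame table (time_h, x_um, y_um).

    Isotropic random steps of length speed*dt per frame interval (or
    straight-line motion when ``directed``), matching the ~2-3 h sampling of
    the motility assay.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, field_um, n_nuclei)
    y = rng.uniform(0, field_um, n_nuclei)
    theta0 = rng.uniform(0, 2 * np.pi, n_nuclei)
    rows = []
    for fi in range(n_frames):
        t = fi * dt_h
        for i in range(n_nuclei):
            rows.append({"time_h": t, "x_um": x[i], "y_um": y[i]})
        step = speed_um_h * dt_h
        theta = theta0 if directed else rng.uniform(0, 2 * np.pi, n_nuclei)
        x = x + step * np.cos(theta)
        y = y + step * np.sin(theta)
    return pd.DataFrame(rows)
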