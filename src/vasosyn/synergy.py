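"""Additive-vs-measured synergy decomposition and related comparisons.

On the log2 fold-change scale, independent stressor action predicts an
additive combined effect: log2FC(additive) = log2FC(metabolic) +
log2FC(humoral).  The synergy index is the departure of the measured
combined-stressor effect from that prediction.  A through-origin scatter
slope of single-stressor vs combined log2FC over the combined-stressor DEG
set summarizes the same question at the transcriptome level: slope near 1
means the single stressor reproduces the combined effect, slope well below 1
means most combined effects are absent under the single stressor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CATEGORIES = ("none", "metabolic", "humoral", "additive", "synergistic_up", "synergistic_down")


def additive_prediction(log2fc_met: float, log2fc_hum: float) -> float:
    """Additive combined-effect prediction on the log2 scale."""
    return log2fc_met + log2fc_hum


def synergy_index(log2fc_all: float, log2fc_additive: float) -> float:
    """Measured minus additive combined log2FC; >0 means over-additivity."""
    return log2fc_all - log2fc_additive


@dataclass
class SlopeResult:
    slope: float
    n_genes: int
    gene_set_label: str
    x_condition: str
    y_condition: str


def scatter_slope(
    x: np.ndarray | pd.Series,
    y: np.ndarray | pd.Series,
    gene_set_label: str = "",
    x_condition: str = "",
    y_condition: str = "",
) -> SlopeResult:
    """Least-squares slope of the through-origin regression y = beta*x.

    beta = sum(x*y) / sum(x^2), the closed form for regression without
    intercept.  Pairs with a NaN coordinate are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 2:
        raise ValueError("need at least 2 points for a slope")
    sxx = float(np.sum(x * x))
    if sxx == 0.0:
        raise ValueError("all x values are zero; slope undefined")
    return SlopeResult(
        slope=float(np.sum(x * y) / sxx),
        n_genes=int(len(x)),
        gene_set_label=gene_set_label,
        x_condition=x_condition,
        y_condition=y_condition,
    )


def build_synergy_table(
    log2fc_met: pd.Series, log2fc_hum: pd.Series, log2fc_all: pd.Series
) -> pd.DataFrame:
    """Per-gene synergy decomposition from the three condition log2FCs."""
    df = pd.DataFrame(
        {"log2fc_met": log2fc_met, "log2fc_hum": log2fc_hum, "log2fc_all": log2fc_all}
    )
    df["log2fc_additive"] = df["log2fc_met"] + df["log2fc_hum"]
    df["synergy_index"] = df["log2fc_all"] - df["log2fc_additive"]
    return df


def classify_gene(
    synergy_idx: float,
    threshold_log2fc: float,
    deg_met: bool,
    deg_hum: bool,
    deg_all: bool,
) -> str:
    """Assign a per-gene interaction category.

    synergistic_up/down: combined-condition DEG whose synergy index exceeds
    the fold-change threshold in magnitude (sign gives direction);
    metabolic/humoral: only that single-stressor flag set and no material
    synergy; additive: combined DEG explained by both single stressors;
    none: otherwise.
    """
    material = np.isfinite(synergy_idx) and abs(synergy_idx) >= threshold_log2fc
    if deg_all and material:
        return "synergistic_up" if synergy_idx > 0 else "synergistic_down"
    if deg_met and not deg_hum and not material:
        return "metabolic"
    if deg_hum and not deg_met and not material:
        return "humoral"
    if deg_all and deg_met and deg_hum and not material:
        return "additive"
    return "none"


def classify_table(
    table: pd.DataFrame,
    threshold_log2fc: float,
    deg_flags: pd.DataFrame,
) -> pd.DataFrame:
    """Vectorized `classify_gene` over a synergy table.

    ``deg_flags`` is a gene-indexed DataFrame with boolean columns
    ``MET``, ``HUM``, ``ALL``.
    """
    out = table.copy()
    flags = deg_flags.reindex(out.index).fillna(False)
    cats = [
        classify_gene(si, threshold_log2fc, bool(m), bool(h), bool(a))
        for si, m, h, a in zip(
            out["synergy_index"], flags["MET"], flags["HUM"], flags["ALL"]
        )
    ]
    out["category"] = pd.Categorical(cats, categories=list(CATEGORIES))
    return out


def reconcile_sets(
    deg_sets: dict[str, set],
    effects: dict[str, pd.DataFrame],
    conditions: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """CI-based reconciliation of two apparently different DEG sets.

    A gene unique to one condition's DEG list may be missing from the other
    only because of the stringent triple filter.  For each such gene we ask
    whether the *other* condition's confidence interval covers the first
    condition's point estimate; if so the two conditions act concordantly on
    the gene despite its absence from one list.

    ``effects`` maps condition -> gene-indexed frame with columns ``effect``,
    ``ci_low``, ``ci_high``.  Returns a per-gene table with membership and
    a ``verdict`` in {shared, concordant, discordant}; Venn-style counts are
    available via :func:`reconciliation_summary`.
    """
    if conditions is None:
        conditions = tuple(deg_sets)  # type: ignore[assignment]
    if len(conditions) != 2:
        raise ValueError("reconcile_sets compares exactly two conditions")
    a, b = conditions
    rows = []
    for gene in sorted(deg_sets[a] | deg_sets[b]):
        in_a = gene in deg_sets[a]
        in_b = gene in deg_sets[b]
        if in_a and in_b:
            verdict = "shared"
        else:
            # CI of the condition where the gene is missing, point estimate
            # of the condition where it was detected
            present, absent = (a, b) if in_a else (b, a)
            point = effects[present].at[gene, "effect"] if gene in effects[present].index else np.nan
            if gene in effects[absent].index:
                lo = effects[absent].at[gene, "ci_low"]
                hi = effects[absent].at[gene, "ci_high"]
            else:
                lo = hi = np.nan
            if np.isfinite(point) and np.isfinite(lo) and np.isfinite(hi):
                verdict = "concordant" if lo <= point <= hi else "discordant"
            else:
                verdict = "discordant"
        rows.append(
            {"gene_id": gene, f"in_{a}": in_a, f"in_{b}": in_b, "verdict": verdict}
        )
    if not rows:
        return pd.DataFrame(
            columns=[f"in_{a}", f"in_{b}", "verdict"],
            index=pd.Index([], name="gene_id"),
        )
    return pd.DataFrame(rows).set_index("gene_id")


def reconciliation_summary(table: pd.DataFrame) -> dict:
    """Venn counts and concordance fractions from a reconciliation table."""
    in_cols = [c for c in table.columns if c.startswith("in_")]
    a_col, b_col = in_cols
    both = int((table[a_col] & table[b_col]).sum())
    only_a = int((table[a_col] & ~table[b_col]).sum())
    only_b = int((~table[a_col] & table[b_col]).sum())
    unique = table[table["verdict"] != "shared"]
    n_unique = len(unique)
    concordant = int((unique["verdict"] == "concordant").sum())
    return {
        "shared": both,
        f"only_{a_col[3:]}": only_a,
        f"only_{b_col[3:]}": only_b,
        "unique_total": n_unique,
        "unique_concordant": concordant,
        "concordance_fraction": (concordant / n_unique) if n_unique else float("nan"),
    }


def enrichment_score(
    intersection_size: int,
    query_size: int,
    term_size: int,
    effective_domain_size: int,
) -> float:
    """Fold-enrichment score of a gene-set overlap.

    E = (intersection/query) / (term/domain): the observed share of the
    query annotated to the term relative to the share expected by chance.
    """
    i, q, t, d = (int(intersection_size), int(query_size), int(term_size),
                  int(effective_domain_size))
    if q <= 0 or t <= 0:
        raise ValueError("query and term sizes must be positive")
    if d <= 0:
        raise ValueError("effective domain size must be positive")
    if i < 0 or i > min(q, t):
        raise ValueError("intersection must be within [0, min(query, term)]")
    if t > d:
        raise ValueError("term size cannot exceed the domain size")
    return (i / q) / (t / d)


def export_mesh(table: pd.DataFrame) -> pd.DataFrame:
    """Long-format surface table of measured, additive and difference log2FC.

    One row per gene with the three value columns used for mesh/surface
    plots; lossless with respect to the synergy table columns it draws on.
    """
    if table.empty:
        raise ValueError("empty synergy table")
    out = pd.DataFrame(
        {
            "gene_id": table.index,
            "measured_log2fc": table["log2fc_all"].to_numpy(),
            "additive_log2fc": table["log2fc_additive"].to_numpy(),
            "difference_log2fc": table["synergy_index"].to_numpy(),
        }
    )
    return out
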