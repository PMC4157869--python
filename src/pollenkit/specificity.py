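"""Multi-stage pollen-specific gene identification.

The pipeline mirrors a cross-platform verification strategy: genes are
called pollen-specific from sequencing-tag (MPSS-style) TPM profiles,
restricted to highly expressed candidates, screened against microarray
profiles for cross-platform inconsistency, and finally verified by an
anther-over-other fold ratio in RNA-Seq profiles.  A control-relative
log2 transform prepares tables for heat-map display.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import (
    ConfigurationError,
    ExpressionTable,
    ValidationError,
    get_logger,
)

log = get_logger("specificity")

NO_PROBE = "no_probe"
INCONSISTENT = "inconsistent"
CONSISTENT = "consistent"


@dataclass(frozen=True)
class SpecificityCriteria:
    """Thresholds of the calling/verification pipeline (TPM scale).

    tau_on: minimum abundance in at least one pollen-classed library for a
        gene to count as expressed in pollen.
    tau_off: maximum abundance tolerated in every non-pollen library
        (inclusive; 0 means strictly undetected elsewhere).
    min_tpm_high: high-expression cut, applied strictly ('more than').
    array_ratio: (max vegetative)/(max pollen) at or above which the
        microarray profile contradicts the call ('similar or higher').
    array_abs_ceiling: optional absolute vegetative-intensity ceiling that
        also flags a gene even when pollen intensity is higher still.
    fold_required: required anther fold over the best other tissue,
        inclusive ('at least').
    pseudocount: added to numerator and denominator of every ratio; 0 is
        allowed, and a zero denominator then yields +inf fold (passes).
    """

    tau_on: float = 5.0
    tau_off: float = 0.0
    min_tpm_high: float = 1000.0
    array_ratio: float = 1.0
    array_abs_ceiling: float | None = None
    fold_required: float = 5.0
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        for name in ("tau_on", "tau_off", "min_tpm_high", "array_ratio", "pseudocount"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.fold_required <= 1:
            raise ValidationError("fold_required must exceed 1")


def call_pollen_specific(
    mpss: ExpressionTable, crit: SpecificityCriteria = SpecificityCriteria()
) -> set[str]:
    """Genes expressed in pollen (max over pollen libraries >= tau_on) and
    silent elsewhere (max over non-pollen libraries <= tau_off)."""
    if mpss.platform != "mpss":
        raise ValidationError(f"expected an mpss table, got {mpss.platform!r}")
    pollen = mpss.tissues_of_class("pollen", "anther")
    others = [t for t in mpss.tissue_ids if t not in pollen]
    if not pollen:
        raise ConfigurationError("no pollen-classed tissue in the MPSS table")
    if not others:
        raise ConfigurationError("no non-pollen tissue to assess specificity against")
    on = mpss.values[pollen].max(axis=1) >= crit.tau_on
    off = mpss.values[others].max(axis=1) <= crit.tau_off
    called = set(mpss.values.index[on & off])
    log.info("specificity call: %d/%d genes pollen-specific", len(called), len(mpss.gene_ids))
    return called


def select_high_expression(
    genes: set[str],
    mpss: ExpressionTable,
    crit: SpecificityCriteria = SpecificityCriteria(),
) -> set[str]:
    """Genes whose maximum pollen-library abundance strictly exceeds
    ``min_tpm_high``."""
    unknown = genes - set(mpss.gene_ids)
    if unknown:
        raise ValidationError(f"genes absent from the MPSS table: {sorted(unknown)[:5]}")
    pollen = mpss.tissues_of_class("pollen", "anther")
    ids = sorted(genes)
    keep = set(
        np.array(ids)[mpss.values.loc[ids, pollen].max(axis=1) > crit.min_tpm_high]
    )
    log.info("high-expression filter (> %g TPM): %d/%d genes kept",
             crit.min_tpm_high, len(keep), len(genes))
    return keep


def verify_microarray(
    genes: set[str],
    array: ExpressionTable,
    crit: SpecificityCriteria = SpecificityCriteria(),
) -> dict[str, str]:
    """Per-gene microarray status: no_probe / inconsistent / consistent.

    Inconsistent means (max vegetative + pseudocount)/(max pollen +
    pseudocount) >= array_ratio, or the optional absolute vegetative
    ceiling is reached.
    """
    if array.platform != "microarray":
        raise ValidationError(f"expected a microarray table, got {array.platform!r}")
    veg = array.tissues_of_class("vegetative")
    pol = array.tissues_of_class("pollen", "anther")
    if not veg or not pol:
        raise ConfigurationError("microarray table needs vegetative and pollen tissues")
    status: dict[str, str] = {}
    for gene in sorted(genes):
        if gene not in array.values.index:
            status[gene] = NO_PROBE
            continue
        v = array.values.loc[gene, veg].max()
        p = array.values.loc[gene, pol].max()
        ratio = (v + crit.pseudocount) / (p + crit.pseudocount) if (
            p + crit.pseudocount
        ) > 0 else np.inf
        flagged = ratio >= crit.array_ratio
        if crit.array_abs_ceiling is not None and v >= crit.array_abs_ceiling:
            flagged = True
        status[gene] = INCONSISTENT if flagged else CONSISTENT
    counts = pd.Series(status).value_counts()
    log.info("microarray screen: %s", counts.to_dict())
    return status


def verify_rnaseq(
    genes: set[str],
    rnaseq: ExpressionTable,
    crit: SpecificityCriteria = SpecificityCriteria(),
    target_class: str = "anther",
) -> pd.DataFrame:
    """Anther-over-best-other fold per gene; pass iff fold >= fold_required.

    Returns a DataFrame indexed by gene with columns ``rnaseq_fold`` and
    ``rnaseq_pass``.
    """
    targets = rnaseq.tissues_of_class(target_class)
    if len(targets) != 1:
        raise ConfigurationError(
            f"expected exactly one {target_class!r}-classed tissue, found {len(targets)}"
        )
    target = targets[0]
    others = [t for t in rnaseq.tissue_ids if t != target]
    unknown = genes - set(rnaseq.gene_ids)
    if unknown:
        raise ValidationError(f"genes absent from the RNA-Seq table: {sorted(unknown)[:5]}")
    ids = sorted(genes)
    if not ids:
        return pd.DataFrame(columns=["rnaseq_fold", "rnaseq_pass"])
    num = rnaseq.values.loc[ids, target] + crit.pseudocount
    den = rnaseq.values.loc[ids, others].max(axis=1) + crit.pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(den > 0, num / den, np.inf)
    out = pd.DataFrame(
        {"rnaseq_fold": fold, "rnaseq_pass": fold >= crit.fold_required}, index=ids
    )
    log.info("RNA-Seq verification: %d/%d genes at fold >= %g (%.1f%%)",
             int(out.rnaseq_pass.sum()), len(ids), crit.fold_required,
             100 * out.rnaseq_pass.mean() if len(ids) else float("nan"))
    return out


@dataclass
class VerificationReport:
    """Per-gene outcomes plus stage counts for a full pipeline run."""

    per_gene: pd.DataFrame  # called_specific, high_expression, array_status,
                            # rnaseq_fold, rnaseq_pass, final_pass
    stage_counts: dict[str, int]
    rnaseq_pass_fraction: float

    @property
    def final_ids(self) -> set[str]:
        return set(self.per_gene.index[self.per_gene.final_pass])

    def to_frame(self) -> pd.DataFrame:
        return self.per_gene.copy()


def run_pipeline(
    mpss: ExpressionTable,
    array: ExpressionTable,
    rnaseq: ExpressionTable,
    crit: SpecificityCriteria = SpecificityCriteria(),
) -> VerificationReport:
    """Call -> high expression -> microarray screen -> RNA-Seq verification.

    Genes flagged inconsistent by the microarray screen are excluded before
    RNA-Seq verification; genes without a probe advance.  Stage survivor
    counts are monotonically non-increasing.
    """
    called = call_pollen_specific(mpss, crit)
    high = select_high_expression(called, mpss, crit)
    # status is computed for every called gene so the probe-coverage count
    # is available, but only high-expression genes can be excluded
    array_status = verify_microarray(called, array, crit)
    advancing = {g for g in high if array_status[g] != INCONSISTENT}
    rnaseq_result = verify_rnaseq(advancing, rnaseq, crit)

    genes = sorted(mpss.gene_ids)
    df = pd.DataFrame(index=genes)
    df["called_specific"] = [g in called for g in genes]
    df["high_expression"] = [g in high for g in genes]
    df["array_status"] = [array_status.get(g, "") for g in genes]
    df["rnaseq_fold"] = [
        float(rnaseq_result.rnaseq_fold.get(g, np.nan)) for g in genes
    ]
    df["rnaseq_pass"] = [bool(rnaseq_result.rnaseq_pass.get(g, False)) for g in genes]
    df["final_pass"] = df.rnaseq_pass & df.index.isin(sorted(advancing))

    n_pass = int(rnaseq_result.rnaseq_pass.sum()) if len(rnaseq_result) else 0
    counts = {
        "input": len(genes),
        "called_specific": len(called),
        "with_probe": sum(s != NO_PROBE for s in array_status.values()),
        "high_expression": len(high),
        "advancing_to_rnaseq": len(advancing),
        "rnaseq_pass": n_pass,
    }
    fraction = n_pass / len(advancing) if advancing else float("nan")
    log.info("pipeline stage counts: %s (RNA-Seq pass fraction %.4f)", counts, fraction)
    return VerificationReport(df, counts, fraction)


# ---------------------------------------------------------------------------
# Heat-map transform


@dataclass
class HeatmapMatrix:
    """log2 control-relative expression matrix for heat-map display."""

    matrix: pd.DataFrame
    control_tissue: str
    pseudocount: float


def heatmap_matrix(
    table: ExpressionTable, control_tissue: str, pseudocount: float = 1.0
) -> HeatmapMatrix:
    """Entrywise log2((v + pseudocount)/(v_control + pseudocount)).

    The control column is exactly zero by construction (the control is its
    own reference).
    """
    if control_tissue not in table.tissue_ids:
        raise ConfigurationError(
            f"control tissue {control_tissue!r} not in table ({table.tissue_ids})"
        )
    if pseudocount < 0:
        raise ValidationError("pseudocount must be non-negative")
    control = table.values[control_tissue] + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        mat = np.log2(
            (table.values.add(pseudocount)).div(control, axis=0)
        )
    mat[control_tissue] = 0.0
    return HeatmapMatrix(mat, control_tissue, pseudocount)


def plot_heatmap(hm: HeatmapMatrix, path: str) -> None:
    """Render a basic red/black/green heat-map image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    finite = hm.matrix.replace([np.inf, -np.inf], np.nan)
    lim = float(np.nanmax(np.abs(finite.to_numpy()))) or 1.0
    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * len(hm.matrix.columns)), max(3, 0.12 * len(hm.matrix)))
    )
    im = ax.imshow(finite.to_numpy(), aspect="auto", cmap="RdYlGn_r", vmin=-lim, vmax=lim)
    ax.set_xticks(range(len(hm.matrix.columns)))
    ax.set_xticklabels(hm.matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_ylabel(f"{len(hm.matrix)} genes")
    fig.colorbar(im, label=f"log2 ratio vs {hm.control_tissue}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
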