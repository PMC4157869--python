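"""Synthetic fixtures with known planted truth: multi-platform expression
panels, promoter sets with planted cis-elements, a two-AhdI-site test
plasmid, and PCR templates.

Every generator is a pure function of its parameters and seed, so each
downstream stage can be tested against the planted truth without any
external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import (
    ExpressionTable,
    GenomicInterval,
    SequenceRecord,
    ValidationError,
    get_logger,
    reverse_complement,
)
from .cloning import DNAMolecule, REGISTRY, scan_sites
from .motifs import MotifHit

log = get_logger("synthetic_data")

_BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, length: int) -> str:
    """i.i.d. uniform A/C/G/T background sequence."""
    return "".join(rng.choice(_BASES, size=length))


# ---------------------------------------------------------------------------
# Expression panels

# Tissue panels mirroring the surveyed datasets: a 12-library MPSS panel,
# an 8-sample and a 3-sample microarray panel, and a 10-tissue RNA-Seq
# panel with a single anther sample.
TISSUE_PANELS: dict[str, tuple[str, list[tuple[str, str]]]] = {
    "mpss12": ("mpss", [
        ("germinating_seeds_3d", "other"),
        ("germinating_seedlings_10d", "vegetative"),
        ("young_leaves_14d", "vegetative"),
        ("young_roots_14d", "vegetative"),
        ("mature_leaves_60d", "vegetative"),
        ("mature_roots_60d", "vegetative"),
        ("stems_60d", "vegetative"),
        ("immature_panicles", "other"),
        ("mature_pollen", "pollen"),
        ("meristematic_tissues", "vegetative"),
        ("ovary_and_mature_stigma", "other"),
        ("developing_seeds", "other"),
    ]),
    "array8": ("microarray", [
        ("callus", "vegetative"),
        ("leaves", "vegetative"),
        ("roots", "vegetative"),
        ("uninucleate_microspores", "other"),
        ("bicellular_pollen", "pollen"),
        ("tricellular_pollen", "pollen"),
        ("mature_pollen", "pollen"),
        ("germinated_pollen", "pollen"),
    ]),
    "array3": ("microarray", [
        ("seedling", "vegetative"),
        ("pollen_at_anthesis", "pollen"),
        ("sperm_at_anthesis", "other"),
    ]),
    "rnaseq10": ("rnaseq", [
        ("shoots", "vegetative"),
        ("leaves_20d", "vegetative"),
        ("pre_emergence_inflorescence", "other"),
        ("post_emergence_inflorescence", "other"),
        ("anther", "anther"),
        ("pistil", "other"),
        ("seed_5dap", "other"),
        ("seed_10dap", "other"),
        ("embryo_25dap", "other"),
        ("endosperm_25dap", "other"),
    ]),
}


@dataclass(frozen=True)
class PanelParams:
    """Conditions for the multi-platform expression simulation.

    Abundances are TPM-scale.  Planted pollen-specific genes sit at
    ``specific_level`` in pollen/anther-classed tissues and at
    ``background_level`` elsewhere; all other genes sit at
    ``background_level`` everywhere.  Noise is multiplicative log-normal:
    value = level * exp(N(0, noise_sd^2)).
    """

    n_genes: int = 500
    n_specific: int = 50
    panels: tuple[str, ...] = ("mpss12", "array8", "rnaseq10")
    specific_level: float = 2000.0
    background_level: float = 1.0
    leak_fraction: float = 0.1
    probe_missing_fraction: float = 0.0
    noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_specific > self.n_genes:
            raise ValidationError("n_specific exceeds n_genes")
        if self.specific_level <= 0 or self.background_level <= 0:
            raise ValidationError("expression levels must be positive")
        if not 0.0 <= self.leak_fraction <= 1.0:
            raise ValidationError("leak_fraction must lie in [0, 1]")
        if not 0.0 <= self.probe_missing_fraction <= 1.0:
            raise ValidationError("probe_missing_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        unknown = [p for p in self.panels if p not in TISSUE_PANELS]
        if unknown:
            raise ValidationError(f"unknown tissue panels: {unknown}")


@dataclass(frozen=True)
class PanelTruth:
    """Planted ground truth for one simulated panel set."""

    specific_ids: frozenset[str]
    leaky_ids: frozenset[str]
    probe_missing_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.leaky_ids <= self.specific_ids:
            raise ValidationError("leaky_ids must be a subset of specific_ids")


def simulate_expression_panel(
    params: PanelParams,
) -> tuple[dict[str, ExpressionTable], PanelTruth]:
    """Simulate one ExpressionTable per requested panel plus planted truth.

    Leaky genes additionally express one vegetative tissue near
    ``specific_level`` in microarray panels only (emulating genes whose
    array profile contradicts their sequencing-based call); probe-missing
    genes are dropped from microarray tables only.
    """
    rng = np.random.default_rng(params.seed)
    gene_ids = [f"G{i + 1:05d}" for i in range(params.n_genes)]

    specific = sorted(
        rng.choice(gene_ids, size=params.n_specific, replace=False)
    )
    n_leaky = int(round(params.leak_fraction * params.n_specific))
    leaky = sorted(rng.choice(specific, size=n_leaky, replace=False))
    n_missing = int(round(params.probe_missing_fraction * params.n_specific))
    missing_pool = sorted(set(specific) - set(leaky))
    if n_missing > len(missing_pool):
        raise ValidationError(
            "probe_missing_fraction and leak_fraction together exceed the planted set"
        )
    probe_missing = sorted(rng.choice(missing_pool, size=n_missing, replace=False))

    truth = PanelTruth(frozenset(specific), frozenset(leaky), frozenset(probe_missing))
    specific_set = set(specific)

    tables: dict[str, ExpressionTable] = {}
    for panel in params.panels:
        platform, tissue_spec = TISSUE_PANELS[panel]
        tissues = [t for t, _ in tissue_spec]
        classes = dict(tissue_spec)
        level = np.full((params.n_genes, len(tissues)), params.background_level)
        on_cols = [
            j for j, t in enumerate(tissues) if classes[t] in ("pollen", "anther")
        ]
        spec_rows = [i for i, g in enumerate(gene_ids) if g in specific_set]
        for i in spec_rows:
            level[i, on_cols] = params.specific_level
        if platform == "microarray":
            veg_cols = [j for j, t in enumerate(tissues) if classes[t] == "vegetative"]
            for gid in leaky:
                i = gene_ids.index(gid)
                level[i, rng.choice(veg_cols)] = params.specific_level
        noise = (
            np.exp(rng.normal(0.0, params.noise_sd, size=level.shape))
            if params.noise_sd > 0
            else 1.0
        )
        df = pd.DataFrame(level * noise, index=gene_ids, columns=tissues)
        if platform == "microarray" and probe_missing:
            df = df.drop(index=probe_missing)
        tables[panel] = ExpressionTable(df, classes, platform)
    log.info(
        "simulated panels %s: %d genes, %d specific (%d leaky, %d probe-missing)",
        list(params.panels), params.n_genes, params.n_specific,
        len(leaky), len(probe_missing),
    )
    return tables, truth


def simulate_stagecount_panel(
    n_specific: int = 1013,
    n_probe_missing: int = 212,
    n_high: int = 70,
    n_inconsistent: int = 3,
    n_low_fold: int = 2,
    low_folds: tuple[float, ...] = (2.6, 2.9),
    n_background: int = 87,
    high_level: float = 1500.0,
    mid_level: float = 300.0,
) -> dict[str, ExpressionTable]:
    """Deterministic panel whose pipeline stage counts follow directly from
    its composition, for bookkeeping tests at realistic cohort sizes.

    The panel plants ``n_specific`` pollen-specific genes of which
    ``n_probe_missing`` (all outside the high-expression tier) lack a
    microarray probe, ``n_high`` exceed the high-expression cut,
    ``n_inconsistent`` of those are given a contradicting vegetative array
    profile, and ``n_low_fold`` of the remainder get anther folds
    ``low_folds`` (others fold far above).  With pseudocount 0 the pipeline
    therefore reports ``n_specific - n_probe_missing`` genes with probes
    and ``n_high - n_inconsistent`` genes advancing to RNA-Seq.
    """
    if n_high + n_probe_missing > n_specific:
        raise ValidationError("probe-missing and high tiers exceed n_specific")
    if n_inconsistent + n_low_fold > n_high:
        raise ValidationError("inconsistent and low-fold tiers exceed n_high")
    if len(low_folds) != n_low_fold:
        raise ValidationError("need one fold value per low-fold gene")
    specific = [f"P{i + 1:05d}" for i in range(n_specific)]
    background = [f"B{i + 1:05d}" for i in range(n_background)]
    genes = specific + background
    high = specific[:n_high]
    inconsistent = high[:n_inconsistent]
    low_fold = high[n_inconsistent:n_inconsistent + n_low_fold]
    probe_missing = specific[n_high:n_high + n_probe_missing]

    def frame(panel: str) -> tuple[pd.DataFrame, dict[str, str], str]:
        platform, tissue_spec = TISSUE_PANELS[panel]
        tissues = [t for t, _ in tissue_spec]
        classes = dict(tissue_spec)
        df = pd.DataFrame(0.0, index=genes, columns=tissues)
        return df, classes, platform

    mpss, m_classes, _ = frame("mpss12")
    mpss.loc[background, :] = 0.5
    mpss.loc[specific, "mature_pollen"] = mid_level
    mpss.loc[high, "mature_pollen"] = high_level

    array, a_classes, _ = frame("array8")
    pollen_cols = [t for t, c in a_classes.items() if c == "pollen"]
    array.loc[:, :] = 1.0
    array.loc[specific, pollen_cols] = high_level
    array.loc[inconsistent, "callus"] = high_level  # similar-or-higher profile
    array = array.drop(index=probe_missing)

    rnaseq, r_classes, _ = frame("rnaseq10")
    rnaseq.loc[:, :] = 1.0
    rnaseq.loc[specific, "anther"] = 2000.0
    for gid, fold in zip(low_fold, low_folds):
        rnaseq.loc[gid, "anther"] = 100.0 * fold
        rnaseq.loc[gid, "pre_emergence_inflorescence"] = 100.0

    return {
        "mpss12": ExpressionTable(mpss, m_classes, "mpss"),
        "array8": ExpressionTable(array, a_classes, "microarray"),
        "rnaseq10": ExpressionTable(rnaseq, r_classes, "rnaseq"),
    }


# ---------------------------------------------------------------------------
# Promoters with planted motifs


def simulate_promoter_set(
    n: int,
    length: int,
    plant_motifs: dict[str, float],
    seed: int = 0,
) -> tuple[list[SequenceRecord], list[MotifHit]]:
    """Uniform-background promoters with motifs planted at known positions.

    Each motif is planted independently per promoter with its given
    probability, at a uniformly chosen position that does not overlap a
    previously planted motif.  Truth positions follow the hit convention:
    1-based distance of the motif's 3'-most base from the base immediately
    upstream of the start codon (the promoter's last base is position 1).
    """
    if n < 1 or length < 1:
        raise ValidationError("need n >= 1 promoters of positive length")
    for motif, prob in plant_motifs.items():
        if len(motif) > length:
            raise ValidationError(f"motif {motif!r} longer than the promoter")
        if not 0.0 <= prob <= 1.0:
            raise ValidationError(f"planting probability for {motif!r} not in [0, 1]")
    rng = np.random.default_rng(seed)
    promoters: list[SequenceRecord] = []
    truth: list[MotifHit] = []
    for i in range(n):
        pid = f"prom{i + 1:03d}"
        seq = list(random_dna(rng, length))
        occupied: list[tuple[int, int]] = []
        for motif in sorted(plant_motifs):
            if rng.random() >= plant_motifs[motif]:
                continue
            m = len(motif)
            placed = False
            for _ in range(200):
                start = int(rng.integers(0, length - m + 1))
                if all(start + m <= a or start >= b for a, b in occupied):
                    placed = True
                    break
            if not placed:
                raise ValidationError(
                    f"could not place motif {motif!r} in promoter {pid} "
                    "without overlap; promoters too short or too crowded"
                )
            seq[start:start + m] = list(motif)
            occupied.append((start, start + m))
            truth.append(MotifHit(pid, motif, length - (start + m - 1), "+"))
        promoters.append(SequenceRecord(pid, "".join(seq)))
    truth.sort(key=lambda h: (h.promoter_id, h.upstream_pos, h.motif))
    return promoters, truth


# ---------------------------------------------------------------------------
# Test plasmid and PCR templates

AHDI_SITE_FWD = "GACAATAAGTC"  # central T -> 3'-T overhang on the upstream side
AHDI_SITE_REV = reverse_complement(AHDI_SITE_FWD)  # GACTTATTGTC
_HINDIII = "AAGCTT"
_NCOI = "CCATGG"


def _spurious_spans(
    seq: str, allowed: dict[str, set[int]]
) -> list[tuple[int, int]]:
    """0-based [start, end) spans of recognition-site matches (circular
    scan) other than the allowed 1-based positions per enzyme."""
    mol = DNAMolecule(seq, "circular")
    bad: list[tuple[int, int]] = []
    for enz_name, positions in allowed.items():
        enz = REGISTRY[enz_name]
        for h in scan_sites(mol, enz):
            if h.position not in positions:
                bad.append((h.position - 1, h.position - 1 + len(enz.recognition)))
    return bad


def build_test_plasmid(
    backbone_len: int = 9000,
    stuffer_len: int = 1305,
    reporter_len: int = 720,
    seed: int = 0,
) -> DNAMolecule:
    """A circular plasmid laid out for T-vector preparation.

    Layout on the top strand: 12-bp prefix containing a HindIII site, an
    AhdI site in forward orientation (GACAATAAGTC, starting at position 13),
    a random stuffer, the same AhdI site inverted, a short spacer, an NcoI
    site whose internal ATG starts a reporter-ORF placeholder, then random
    backbone filler.  With the default 1,305-bp stuffer the two AhdI sites
    start at positions 13 and 1,329.  Random filler is rejection-sampled
    until it creates no spurious AhdI/HindIII/NcoI match, so AhdI digestion
    yields exactly the backbone and stuffer fragments.
    """
    if stuffer_len < 0 or backbone_len < reporter_len + 200:
        raise ValidationError("backbone too short to host the reporter placeholder")
    rng = np.random.default_rng(seed)
    site_len = len(AHDI_SITE_FWD)
    spacer_len = 20

    prefix = random_dna(rng, 3) + _HINDIII + random_dna(rng, 3)
    stuffer = random_dna(rng, stuffer_len)
    spacer = random_dna(rng, spacer_len)
    # reporter placeholder: ORF continuing from the ATG inside CCATGG
    reporter_body = random_dna(rng, reporter_len)
    filler = random_dna(rng, backbone_len - reporter_len)

    seq = list(
        prefix + AHDI_SITE_FWD + stuffer + AHDI_SITE_REV
        + spacer + _NCOI + reporter_body + filler
    )
    p_ahdi1 = len(prefix) + 1                       # 13 by construction
    p_ahdi2 = p_ahdi1 + site_len + stuffer_len      # 1329 with defaults
    p_hind = 4
    p_ncoi = p_ahdi2 + site_len + spacer_len
    atg = p_ncoi + 2                                # ATG inside CCATGG

    # 0-based indices of bases that belong to a fixed element and must not
    # be touched while cleaning up chance recognition-site matches.
    fixed: set[int] = set()
    for start1, element in (
        (p_hind, _HINDIII),
        (p_ahdi1, AHDI_SITE_FWD),
        (p_ahdi2, AHDI_SITE_REV),
        (p_ncoi, _NCOI),
    ):
        fixed.update(range(start1 - 1, start1 - 1 + len(element)))
    allowed = {"AhdI": {p_ahdi1, p_ahdi2}, "HindIII": {p_hind}, "NcoI": {p_ncoi}}

    # Rejection-sample only the random bases under each spurious match.
    for _round in range(200):
        spans = _spurious_spans("".join(seq), allowed)
        if not spans:
            break
        for a, b in spans:
            for i in range(a, b):
                j = i % len(seq)
                if j not in fixed:
                    seq[j] = str(rng.choice(_BASES))
    else:
        raise ValidationError("failed to build a clean plasmid in 200 rounds")

    annotations = (
        ("HindIII", GenomicInterval("plasmid", p_hind, p_hind + 5)),
        ("AhdI_site_1", GenomicInterval("plasmid", p_ahdi1, p_ahdi1 + site_len - 1)),
        ("stuffer", GenomicInterval("plasmid", p_ahdi1 + site_len, p_ahdi2 - 1)),
        ("AhdI_site_2", GenomicInterval("plasmid", p_ahdi2, p_ahdi2 + site_len - 1)),
        ("NcoI", GenomicInterval("plasmid", p_ncoi, p_ncoi + 5)),
        ("reporter", GenomicInterval("plasmid", atg, atg + 3 + reporter_len - 1)),
    )
    plasmid = DNAMolecule(
        "".join(seq), "circular", annotations=annotations, name="pDsTGFP_synthetic"
    )
    log.info("built test plasmid: %d bp, AhdI sites at %d and %d",
             len(plasmid.sequence), p_ahdi1, p_ahdi2)
    return plasmid


def simulate_pcr_template(
    promoter: SequenceRecord, flank_len: int = 500, seed: int = 0
) -> SequenceRecord:
    """Embed a promoter in random flanks so that primers matching the
    promoter termini amplify exactly the promoter."""
    if flank_len < 0:
        raise ValidationError("flank_len must be non-negative")
    rng = np.random.default_rng(seed)
    k = min(20, len(promoter.sequence))
    head, tail = promoter.sequence[:k], promoter.sequence[-k:]
    for _ in range(1000):
        template = random_dna(rng, flank_len) + promoter.sequence + random_dna(rng, flank_len)
        if template.count(head) == 1 and template.count(tail) == 1:
            return SequenceRecord(
                f"{promoter.id}_template", template,
                f"promoter {promoter.id} with {flank_len}-bp flanks",
            )
    raise ValidationError("failed to build an unambiguous PCR template")
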