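"""In-silico restriction cloning: degenerate site scanning, staggered
digestion with overhang bookkeeping, T-vector preparation, A-tailing,
TA ligation with orientation enumeration, and virtual PCR.

Double-stranded DNA is represented by its top strand (5'->3').  Overhangs
are stored per end; the sequence of a bottom-strand overhang is recorded as
read 5'->3' along the bottom strand, so that two sticky ends are ligatable
exactly when one overhang equals the reverse complement of the other.

At the LEFT end of a linear molecule a 5' overhang protrudes on the top
strand (and is a prefix of ``sequence``) while a 3' overhang protrudes on
the bottom strand (stored only in the end descriptor).  At the RIGHT end
the roles swap: a 3' overhang is a suffix of ``sequence``, a 5' overhang is
on the bottom strand.  With this convention the top strands of two ligated
molecules concatenate exactly, and every overhang base is counted once.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from .io_core import (
    GenomicInterval,
    ValidationError,
    get_logger,
    reverse_complement,
)

log = get_logger("cloning")

FIVE_PRIME = "5'"
THREE_PRIME = "3'"
BLUNT = "blunt"

_IUPAC_REGEX = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


def iupac_to_regex(pattern: str) -> str:
    return "".join(_IUPAC_REGEX[b] for b in pattern.upper())


# ---------------------------------------------------------------------------
# Ends and molecules


@dataclass(frozen=True)
class MoleculeEnd:
    """One end of a linear duplex: overhang sequence plus polarity.

    ``overhang_seq`` is read 5'->3' along the protruding strand and is empty
    iff the end is blunt.
    """

    overhang_seq: str = ""
    polarity: str = BLUNT

    def __post_init__(self) -> None:
        if self.polarity not in (FIVE_PRIME, THREE_PRIME, BLUNT):
            raise ValidationError(f"bad end polarity {self.polarity!r}")
        if (self.polarity == BLUNT) != (self.overhang_seq == ""):
            raise ValidationError("end is blunt iff its overhang is empty")

    @property
    def is_blunt(self) -> bool:
        return self.polarity == BLUNT


def ends_compatible(right: MoleculeEnd, left: MoleculeEnd) -> bool:
    """Can the right end of one molecule ligate to the left end of another?

    Blunt joins blunt; sticky ends require equal polarity and
    reverse-complementary overhangs (so 3'-T anneals 3'-A, and a
    palindromic 5' overhang such as HindIII's AGCT anneals itself).
    """
    if right.is_blunt and left.is_blunt:
        return True
    if right.polarity != left.polarity:
        return False
    return right.overhang_seq == reverse_complement(left.overhang_seq)


BLUNT_END = MoleculeEnd()


@dataclass(frozen=True)
class DNAMolecule:
    """A DNA duplex: top strand, topology, end descriptions, annotations.

    Annotations are (label, interval) pairs in 1-based top-strand
    coordinates and travel with the sequence through digestion/ligation
    when they stay intact.
    """

    sequence: str
    topology: str = "linear"
    left_end: MoleculeEnd | None = None
    right_end: MoleculeEnd | None = None
    annotations: tuple[tuple[str, GenomicInterval], ...] = ()
    name: str = ""

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "circular"):
            raise ValidationError(f"bad topology {self.topology!r}")
        object.__setattr__(self, "sequence", self.sequence.upper())
        if self.topology == "circular":
            if self.left_end is not None or self.right_end is not None:
                raise ValidationError("circular molecules have no ends")
        else:
            if self.left_end is None:
                object.__setattr__(self, "left_end", BLUNT_END)
            if self.right_end is None:
                object.__setattr__(self, "right_end", BLUNT_END)
            self._check_end_consistency()

    def _check_end_consistency(self) -> None:
        left, right = self.left_end, self.right_end
        if left.polarity == FIVE_PRIME and not self.sequence.startswith(left.overhang_seq):
            raise ValidationError("left 5' overhang is not a prefix of the top strand")
        if right.polarity == THREE_PRIME and not self.sequence.endswith(right.overhang_seq):
            raise ValidationError("right 3' overhang is not a suffix of the top strand")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def reverse_complement(self) -> "DNAMolecule":
        """The same physical molecule read from the other strand."""
        n = len(self.sequence)
        # Bottom strand 5'->3': right-end bottom overhang, the complement of
        # the duplex core, then the left-end bottom overhang.
        top = self.sequence
        lo = self.left_end.overhang_seq if (self.left_end and self.left_end.polarity == FIVE_PRIME) else ""
        ro = self.right_end.overhang_seq if (self.right_end and self.right_end.polarity == THREE_PRIME) else ""
        core = top[len(lo): n - len(ro) if ro else n]
        bottom = ""
        if self.right_end and self.right_end.polarity == FIVE_PRIME:
            bottom += self.right_end.overhang_seq
        bottom += reverse_complement(core)
        if self.left_end and self.left_end.polarity == THREE_PRIME:
            bottom += self.left_end.overhang_seq
        if self.is_circular:
            return DNAMolecule(reverse_complement(top), "circular", name=self.name)
        return DNAMolecule(
            bottom,
            "linear",
            left_end=self.right_end,
            right_end=self.left_end,
            name=self.name,
        )


# ---------------------------------------------------------------------------
# Enzymes


@dataclass(frozen=True)
class Enzyme:
    """A within-site restriction endonuclease.

    ``top_cut``/``bottom_cut`` count bases from the recognition pattern's
    5' end to the cut on the top strand and (in top-strand coordinates) the
    bottom strand.  top_cut > bottom_cut leaves 3' overhangs, smaller
    leaves 5' overhangs, equal leaves blunt ends.
    """

    name: str
    recognition: str
    top_cut: int
    bottom_cut: int

    def __post_init__(self) -> None:
        if not self.recognition or set(self.recognition) - set(_IUPAC_REGEX):
            raise ValidationError(f"bad recognition pattern {self.recognition!r}")
        for cut in (self.top_cut, self.bottom_cut):
            if not 0 < cut < len(self.recognition):
                raise ValidationError(
                    f"{self.name}: cut position {cut} outside recognition site"
                )

    @property
    def overhang_length(self) -> int:
        return abs(self.top_cut - self.bottom_cut)

    def regex(self) -> re.Pattern:
        return re.compile(f"(?=({iupac_to_regex(self.recognition)}))")


def _enzyme_from_notation(name: str, notation: str) -> Enzyme:
    """Build an enzyme from slash notation, e.g. 'GACNNN/NNGTC'.

    Only valid for patterns that equal their own reverse complement, where
    the bottom-strand cut mirrors the top-strand cut.
    """
    top_cut = notation.index("/")
    pattern = notation.replace("/", "")
    if reverse_complement(pattern) != pattern:
        raise ValidationError(f"{name}: slash notation needs a self-revcomp pattern")
    return Enzyme(name, pattern, top_cut, len(pattern) - top_cut)


# Registry of modeled enzymes; cut offsets are data, but each entry is
# asserted against the conventional slash notation at import time.
_NOTATION = {
    "AhdI": "GACNNN/NNGTC",
    "XcmI": "CCANNNNN/NNNNTGG",
    "HindIII": "A/AGCTT",
    "NcoI": "C/CATGG",
    "SpeI": "A/CTAGT",
}

REGISTRY: dict[str, Enzyme] = {
    "AhdI": Enzyme("AhdI", "GACNNNNNGTC", 6, 5),
    "XcmI": Enzyme("XcmI", "CCANNNNNNNNNTGG", 8, 7),
    "HindIII": Enzyme("HindIII", "AAGCTT", 1, 5),
    "NcoI": Enzyme("NcoI", "CCATGG", 1, 5),
    "SpeI": Enzyme("SpeI", "ACTAGT", 1, 5),
}

for _name, _enz in REGISTRY.items():
    assert _enz == _enzyme_from_notation(_name, _NOTATION[_name]), _name
    # Patterns equal to their own reverse complement need no bottom-strand
    # scanning pass.
    assert reverse_complement(_enz.recognition) == _enz.recognition, _name


def get_enzyme(name: str) -> Enzyme:
    try:
        return REGISTRY[name]
    except KeyError:
        raise ValidationError(
            f"unknown enzyme {name!r}; registry has {sorted(REGISTRY)}"
        ) from None


# ---------------------------------------------------------------------------
# Site scanning


@dataclass(frozen=True)
class RestrictionSiteHit:
    position: int  # 1-based start of the recognition site on the top strand
    matched: str
    enzyme: str


def scan_sites(mol: DNAMolecule, enz: Enzyme) -> list[RestrictionSiteHit]:
    """All top-strand matches of the recognition pattern, 1-based.

    Circular molecules are scanned across the origin by extending the
    sequence with the first pattern-length-minus-one bases.
    """
    seq = mol.sequence
    plen = len(enz.recognition)
    search_space = seq + seq[: plen - 1] if mol.is_circular else seq
    hits = []
    seen = set()
    for m in enz.regex().finditer(search_space):
        pos0 = m.start() % len(seq) if mol.is_circular else m.start()
        if pos0 in seen:
            continue
        seen.add(pos0)
        hits.append(RestrictionSiteHit(pos0 + 1, m.group(1), enz.name))
    hits.sort(key=lambda h: h.position)
    return hits


# ---------------------------------------------------------------------------
# Digestion


def _cut_ends(enz: Enzyme, site_seq: str) -> tuple[MoleculeEnd, MoleculeEnd]:
    """Ends produced by one cut: (right end of upstream fragment,
    left end of downstream fragment)."""
    lo, hi = sorted((enz.top_cut, enz.bottom_cut))
    region = site_seq[lo:hi]  # top-strand bases between the two strand cuts
    if not region:
        return BLUNT_END, BLUNT_END
    if enz.top_cut > enz.bottom_cut:  # 3' overhangs
        return (
            MoleculeEnd(region, THREE_PRIME),
            MoleculeEnd(reverse_complement(region), THREE_PRIME),
        )
    return (  # 5' overhangs
        MoleculeEnd(reverse_complement(region), FIVE_PRIME),
        MoleculeEnd(region, FIVE_PRIME),
    )


def _annotations_within(
    annotations, frag_start0: int, frag_len: int, total_len: int, circular: bool
):
    """Annotations fully contained in a (possibly wrapping) fragment,
    re-based to fragment coordinates."""
    kept = []
    for label, iv in annotations:
        s0, e0 = iv.start - 1, iv.end - 1
        off_s = (s0 - frag_start0) % total_len if circular else s0 - frag_start0
        off_e = (e0 - frag_start0) % total_len if circular else e0 - frag_start0
        if 0 <= off_s <= off_e < frag_len:
            kept.append(
                (label, GenomicInterval(iv.reference_id, off_s + 1, off_e + 1, iv.strand))
            )
    return tuple(kept)


def digest(mol: DNAMolecule, enz: Enzyme) -> list[DNAMolecule]:
    """Cut at every recognition site, tracking overhangs on each fragment.

    A circular molecule with k sites yields k linear fragments; a linear
    molecule yields k+1 (and is returned unchanged when k = 0).  The total
    top-strand base count is conserved.
    """
    sites = scan_sites(mol, enz)
    if not sites:
        return [mol]
    n = len(mol.sequence)
    plen = len(enz.recognition)

    # Reject sites whose staggered-cut regions overlap (ambiguous products).
    lo_off, hi_off = sorted((enz.top_cut, enz.bottom_cut))
    spans = sorted((h.position - 1 + lo_off, h.position - 1 + hi_off) for h in sites)
    for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
        if a2 < b1:
            raise ValidationError(
                f"{enz.name} cut regions overlap at top-strand positions {a1 + 1} and {a2 + 1}"
            )
    if mol.is_circular and len(spans) > 1:
        a_first, _ = spans[0]
        _, b_last = spans[-1]
        if a_first + n < b_last:
            raise ValidationError(f"{enz.name} cut regions overlap across the origin")

    cuts = []  # (top cut 0-based, right end of upstream, left end of downstream)
    for hit in sites:
        site_seq = hit.matched
        up_right, down_left = _cut_ends(enz, site_seq)
        cuts.append((hit.position - 1 + enz.top_cut, up_right, down_left))

    fragments: list[DNAMolecule] = []
    if mol.is_circular:
        for i, (c_top, up_right, down_left) in enumerate(cuts):
            nxt_c_top, nxt_up_right, _ = cuts[(i + 1) % len(cuts)]
            frag_len = (nxt_c_top - c_top) % n or n
            start0 = c_top % n
            seq = (mol.sequence * 2)[start0: start0 + frag_len]
            fragments.append(
                DNAMolecule(
                    seq,
                    "linear",
                    left_end=down_left,
                    right_end=nxt_up_right,
                    annotations=_annotations_within(
                        mol.annotations, start0, frag_len, n, True
                    ),
                    name=f"{mol.name}_frag{i + 1}" if mol.name else "",
                )
            )
    else:
        bounds = [0] + [c for c, _, _ in cuts] + [n]
        left_ends = [mol.left_end] + [dl for _, _, dl in cuts]
        right_ends = [ur for _, ur, _ in cuts] + [mol.right_end]
        for i, (a, b) in enumerate(zip(bounds, bounds[1:])):
            fragments.append(
                DNAMolecule(
                    mol.sequence[a:b],
                    "linear",
                    left_end=left_ends[i],
                    right_end=right_ends[i],
                    annotations=_annotations_within(mol.annotations, a, b - a, n, False),
                    name=f"{mol.name}_frag{i + 1}" if mol.name else "",
                )
            )
    log.info("%s digest of %d bp (%s): %d sites -> %d fragments",
             enz.name, n, mol.topology, len(sites), len(fragments))
    return fragments


def make_t_vector(plasmid: DNAMolecule, enz: Enzyme = REGISTRY["AhdI"]) -> DNAMolecule:
    """Linearize a two-site plasmid and keep the larger (backbone) fragment,
    validating that both of its ends are 1-nt 3'-T overhangs.

    The backbone carries 3'-T at both ends only when the two sites are in
    inverted orientation so that each contributes its central T to the
    backbone side of the cut; same-orientation sites leave one 3'-A end.
    The discarded stuffer fragment's length is logged.
    """
    if not plasmid.is_circular:
        raise ValidationError("T-vector preparation expects a circular plasmid")
    sites = scan_sites(plasmid, enz)
    if len(sites) != 2:
        raise ValidationError(
            f"expected exactly 2 {enz.name} sites, found {len(sites)}"
        )
    fragments = digest(plasmid, enz)
    fragments.sort(key=lambda f: len(f.sequence), reverse=True)
    backbone, stuffer = fragments
    for side, end in (("left", backbone.left_end), ("right", backbone.right_end)):
        if end.polarity != THREE_PRIME or end.overhang_seq != "T":
            raise ValidationError(
                "not a T-vector: backbone %s end is %s %r, not a 3'-T overhang "
                "(the two %s sites must be in inverted orientation so each "
                "leaves its central T on the backbone)"
                % (side, end.polarity, end.overhang_seq, enz.name)
            )
    log.info("T-vector: backbone %d bp, discarded stuffer %d bp",
             len(backbone.sequence), len(stuffer.sequence))
    return replace(backbone, name=(plasmid.name + "_Tvector") if plasmid.name else "Tvector")


def a_tail(amplicon: DNAMolecule) -> DNAMolecule:
    """Add a single untemplated 3' adenosine to both ends of a blunt duplex
    (Taq terminal transferase activity)."""
    if amplicon.is_circular:
        raise ValidationError("cannot A-tail a circular molecule")
    if not (amplicon.left_end.is_blunt and amplicon.right_end.is_blunt):
        raise ValidationError("A-tailing requires blunt ends (already tailed or digested?)")
    return DNAMolecule(
        amplicon.sequence + "A",
        "linear",
        left_end=MoleculeEnd("A", THREE_PRIME),
        right_end=MoleculeEnd("A", THREE_PRIME),
        annotations=amplicon.annotations,
        name=amplicon.name,
    )


# ---------------------------------------------------------------------------
# Ligation


def _join(a: DNAMolecule, b: DNAMolecule, name: str) -> DNAMolecule:
    """Circularize a + b (right of a onto left of b and right of b onto
    left of a); top strands concatenate exactly."""
    shifted = tuple(
        (label, GenomicInterval(iv.reference_id, iv.start + len(a.sequence),
                                iv.end + len(a.sequence), iv.strand))
        for label, iv in b.annotations
    )
    return DNAMolecule(
        a.sequence + b.sequence,
        "circular",
        annotations=a.annotations + shifted,
        name=name,
    )


def ligate(vector: DNAMolecule, insert: DNAMolecule | None = None) -> list[DNAMolecule]:
    """Enumerate circular ligation products.

    With one molecule: self-circularization if its two ends are compatible.
    With two: both insert orientations are tried; a T-vector plus an
    A-tailed insert yields exactly two products differing by orientation.
    An empty list (no compatible junction) is not an error.
    """
    if vector.is_circular or (insert is not None and insert.is_circular):
        raise ValidationError("ligation inputs must be linear")
    products: list[DNAMolecule] = []
    if insert is None:
        if ends_compatible(vector.right_end, vector.left_end):
            products.append(
                DNAMolecule(vector.sequence, "circular",
                            annotations=vector.annotations,
                            name=vector.name + "_circ" if vector.name else "")
            )
        return products
    for tag, orient in (("fwd", insert), ("rev", insert.reverse_complement())):
        if ends_compatible(vector.right_end, orient.left_end) and ends_compatible(
            orient.right_end, vector.left_end
        ):
            products.append(_join(vector, orient, name=f"ligation_{tag}"))
    log.info("ligation: %d circular product(s)", len(products))
    return products


# ---------------------------------------------------------------------------
# Virtual PCR and orientation verification


@dataclass(frozen=True)
class PrimerPair:
    """Two primers, 5'->3'; annealing is exact and full-length."""

    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for label, p in (("forward", self.forward), ("reverse", self.reverse)):
            if len(p) < 15:
                raise ValidationError(f"{label} primer shorter than 15 nt")
            if set(p.upper()) - set("ACGT"):
                raise ValidationError(f"{label} primer has non-ACGT characters")
        object.__setattr__(self, "forward", self.forward.upper())
        object.__setattr__(self, "reverse", self.reverse.upper())


def in_silico_pcr(template: DNAMolecule, primers: PrimerPair) -> list[DNAMolecule]:
    """Predict amplicons by exact primer placement.

    The forward primer anneals where it matches the top strand; the reverse
    primer anneals where its reverse complement matches the top strand at or
    downstream of the forward match.  The amplicon spans both primers'
    5' ends inclusive.  Circular templates are searched across the origin;
    amplicons longer than the template are impossible.
    """
    seq = template.sequence
    n = len(seq)
    fwd = primers.forward
    rev_rc = reverse_complement(primers.reverse)
    space = seq + seq[: n - 1] if template.is_circular else seq

    def find_all(sub: str) -> list[int]:
        return [m.start() for m in re.finditer(f"(?={re.escape(sub)})", space)]

    amplicons = []
    seen = set()
    for f in find_all(fwd):
        if f >= n:  # forward starts must be canonical positions
            continue
        for r in find_all(rev_rc):
            if r < f:
                continue
            end = r + len(rev_rc)
            length = end - f
            if length > n:
                continue
            key = (f % n, length)
            if key in seen:
                continue
            seen.add(key)
            amplicons.append(
                DNAMolecule(space[f:end], "linear", name=f"amplicon_{f + 1}_{length}bp")
            )
    amplicons.sort(key=lambda a: (a.name, len(a.sequence)))
    return amplicons


# ---------------------------------------------------------------------------
# Molecule <-> FASTA record serialization


def _end_token(end: MoleculeEnd) -> str:
    if end.is_blunt:
        return "blunt"
    return ("3'" if end.polarity == THREE_PRIME else "5'") + end.overhang_seq


def _parse_end_token(token: str) -> MoleculeEnd:
    if token == "blunt":
        return BLUNT_END
    if token.startswith("3'"):
        return MoleculeEnd(token[2:], THREE_PRIME)
    if token.startswith("5'"):
        return MoleculeEnd(token[2:], FIVE_PRIME)
    raise ValidationError(f"bad molecule end token {token!r}")


def molecule_to_record(mol: DNAMolecule, record_id: str | None = None):
    """Encode a molecule as a FASTA record; topology and end overhangs go
    into the description, e.g. ``[left=3'T right=3'T circular=false]``."""
    from .io_core import SequenceRecord

    if mol.is_circular:
        desc = "[circular=true]"
    else:
        desc = (
            f"[left={_end_token(mol.left_end)} "
            f"right={_end_token(mol.right_end)} circular=false]"
        )
    return SequenceRecord(record_id or mol.name or "molecule", mol.sequence, desc)


def record_to_molecule(record) -> DNAMolecule:
    """Decode a FASTA record written by :func:`molecule_to_record`; records
    without end annotations become blunt linear molecules."""
    desc = record.description or ""
    tokens = dict(
        part.split("=", 1)
        for part in desc.strip("[]").split()
        if "=" in part
    )
    if tokens.get("circular", "false").lower() == "true":
        return DNAMolecule(record.sequence, "circular", name=record.id)
    return DNAMolecule(
        record.sequence,
        "linear",
        left_end=_parse_end_token(tokens.get("left", "blunt")),
        right_end=_parse_end_token(tokens.get("right", "blunt")),
        name=record.id,
    )


def verify_orientation(
    products: list[DNAMolecule],
    reporter_rev_primer: str,
    insert_fwd_primer: str,
) -> dict[str, str]:
    """Classify ligation products as insert-toward-reporter or reversed.

    A product is "correct" iff virtual PCR with the insert forward primer
    and the vector-borne reporter reverse primer yields exactly one
    amplicon; of two orientation products exactly one can be correct.
    """
    primers = PrimerPair(insert_fwd_primer, reporter_rev_primer)
    result = {}
    for i, product in enumerate(products):
        key = product.name or f"product_{i + 1}"
        amps = in_silico_pcr(product, primers)
        result[key] = "correct" if len(amps) == 1 else "reversed"
    if products and all(v == "reversed" for v in result.values()):
        log.warning(
            "no product verified as correct; is the reporter reverse primer "
            "present on the vector?"
        )
    return result
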