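"""Designed oligo library construction.

Each library member is a 12-nt barcode followed by a 158-nt variable region
carrying one intron design.  Five subsets are produced:

* ``combinatorial`` — synthetic introns assembled from a catalog of splice
  sites (5'SS, branch site, 3'SS), intron length, branch-to-3'SS distance
  and a 3' U-rich element, placed on a background sequence;
* ``natural`` — full intron sequences inserted with 5-nt exonic flanks at
  the 5' end of the variable region;
* ``mutated`` — combinatorial designs with random point mutations in the
  splice sites, or with mutations around a site selected so the site folds
  into a stem (structure mutants);
* ``two_intron`` — two short introns separated by an exon;
* ``negative_control`` — mock (non-functional) site sequences with the
  combinatorial geometry.

Coordinates are 1-based closed and counted from the barcode's first base,
so the 5'SS of every synthetic intron occupies oligo positions 18-23
(5 nt into the variable region).  The whole design is kept free of ATG
triplets at any offset (the library is transcribed as non-coding RNA);
when a 5'SS itself contains ATG, a stop codon is planted two codons
downstream instead.

The bundled background sequences and "natural" introns are seeded random
synthetic stand-ins for the gene-derived sequences of a real assay (which
are not part of this package); their statistical role — a fixed ATG-free
sequence context — is the same.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd

__all__ = [
    "BARCODE_LEN",
    "REGION_LEN",
    "FIVE_SS_START",
    "SpliceSiteCatalog",
    "DesignFeatures",
    "OligoVariant",
    "generate_barcodes",
    "scrub_start_codons",
    "build_combinatorial_variant",
    "insert_natural_intron",
    "build_two_intron_variant",
    "mutate_for_structure",
    "recover_design_features",
    "random_background",
    "make_synthetic_intron",
    "design_library",
    "LibraryConfig",
    "variants_to_manifest",
    "variants_from_manifest",
]

BARCODE_LEN = 12
REGION_LEN = 158
#: 1-based oligo position (from barcode start) of the first 5'SS base.
FIVE_SS_START = 18
JUNCTION_FLANK = 20

BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")


class DesignError(ValueError):
    pass


# ---------------------------------------------------------------------------
# catalog


@dataclass
class SpliceSiteCatalog:
    """Catalog of splice-site motifs available to the combinatorial design.

    Branch sites may be 2-degenerate templates (leading ``NN``); every
    concrete branch site is 7 nt with the catalytic A at motif position 6.
    """

    five_prime_sites: list = field(
        default_factory=lambda: ["GTATGT", "GTAAGT", "GTATGA", "GTACGT", "GTATGC"]
    )
    branch_sites: list = field(
        default_factory=lambda: ["TACTAAC", "NNCTAAC", "NNCTAAT", "NNTTAAC"]
    )
    three_prime_sites: list = field(default_factory=lambda: ["TAG", "CAG", "AAG"])
    u_elements: list = field(default_factory=lambda: ["ATTTTTAA", "TTTAA", "TAA"])
    control_sites: dict = field(default_factory=dict)

    def __post_init__(self):
        for s in self.five_prime_sites:
            if len(s) != 6:
                raise DesignError(f"5'SS must be 6 nt: {s}")
        for s in self.branch_sites:
            if len(s) != 7 or s[5] != "A":
                raise DesignError(f"branch site must be 7 nt with A at position 6: {s}")
        for s in self.three_prime_sites:
            if len(s) != 3 or not s.endswith("AG"):
                raise DesignError(f"3'SS must be 3 nt ending in AG: {s}")

    @property
    def consensus(self):
        return {"five_ss": "GTATGT", "branch": "TACTAAC", "three_ss": "TAG"}

    def make_control_sites(self, rng: np.random.Generator) -> dict:
        """One mock sequence per site class, drawn once per library.

        Mock sites deliberately avoid the canonical dinucleotides (GT...,
        ...AG, catalytic A context) so they carry no splicing signal.
        """

        def draw(length, avoid):
            for _ in range(1000):
                s = "".join(rng.choice(list(BASES), size=length))
                if "ATG" not in s and not any(a(s) for a in avoid):
                    return s
            raise DesignError("could not draw a mock site")

        self.control_sites = {
            "five_ss": draw(6, [lambda s: s.startswith("GT")]),
            "branch": draw(7, [lambda s: s[5] == "A", lambda s: "TAAC" in s]),
            "three_ss": draw(3, [lambda s: s.endswith("AG")]),
        }
        return self.control_sites


@dataclass
class DesignFeatures:
    five_ss: str
    branch: str
    three_ss: str
    intron_len: int
    bs_to_3ss: int
    u_element: str
    background_id: str = "bg0"

    def validate(self):
        if len(self.five_ss) != 6:
            raise DesignError("5'SS must be 6 nt")
        if len(self.branch) != 7:
            raise DesignError("branch site must be 7 nt")
        if len(self.three_ss) != 3:
            raise DesignError("3'SS must be 3 nt")
        if "N" in self.branch:
            raise DesignError("degenerate branch template must be instantiated first")
        if self.intron_len < 6 + 7 + self.bs_to_3ss:
            raise DesignError("intron too short to fit its sites")
        if self.bs_to_3ss < len(self.u_element) + 3:
            raise DesignError("U element does not fit between branch site and 3'SS")
        return self


@dataclass
class OligoVariant:
    """One designed library member.

    ``introns`` are 1-based closed intervals counted from the barcode's
    first base; ``junctions`` maps junction names to reference sequences
    (nominally 20 nt on each side of the boundary, truncated at oligo ends).
    """

    variant_id: str
    barcode: str
    variable_region: str
    subset_label: str
    features: dict
    introns: list
    junctions: dict = field(default_factory=dict)

    @property
    def sequence(self) -> str:
        return self.barcode + self.variable_region

    def __post_init__(self):
        if len(self.barcode) != BARCODE_LEN:
            raise DesignError("barcode length must be 12")
        if len(self.variable_region) != REGION_LEN:
            raise DesignError("variable region length must be exactly 158")

    def spliced_sequence(self, introns: Sequence[tuple] | None = None) -> str:
        """Oligo sequence with the given introns (default: the designed
        ones) excised."""
        seq = self.sequence
        out = []
        pos = 0
        for s, e in sorted(introns if introns is not None else self.introns):
            out.append(seq[pos : s - 1])
            pos = e
        out.append(seq[pos:])
        return "".join(out)


# ---------------------------------------------------------------------------
# barcodes


def generate_barcodes(
    n: int,
    length: int = BARCODE_LEN,
    min_dist: int = 4,
    seed: int | None = None,
    max_rejections: int = 200_000,
) -> list:
    """Random barcodes with pairwise Levenshtein distance >= ``min_dist``.

    Barcodes never contain ATG (no-start-codon rule).  Fails explicitly
    when ``max_rejections`` candidates in a row are rejected.
    """
    if n < 1:
        raise DesignError("n must be >= 1")
    rng = np.random.default_rng(seed)
    accepted: list[str] = []
    rejections = 0
    while len(accepted) < n:
        cand = "".join(rng.choice(list(BASES), size=length))
        ok = "ATG" not in cand
        if ok:
            for b in accepted:
                d = edlib.align(cand, b, k=min_dist - 1)["editDistance"]
                if d != -1:  # within min_dist - 1: too close
                    ok = False
                    break
        if ok:
            accepted.append(cand)
            rejections = 0
        else:
            rejections += 1
            if rejections > max_rejections:
                raise DesignError(
                    f"could not find {n} barcodes of length {length} at "
                    f"distance >= {min_dist} (stuck after {len(accepted)})"
                )
    return accepted


def decode_barcode(observed: str, barcodes: Sequence[str], max_dist: int = 2):
    """Nearest-neighbour decoding of a (possibly corrupted) barcode.

    Returns the unique barcode within Levenshtein distance <= ``max_dist``,
    or None when no barcode or more than one barcode attains the minimal
    distance.
    """
    best, best_d, ties = None, max_dist + 1, 0
    for b in barcodes:
        d = edlib.align(observed, b, k=max_dist)["editDistance"]
        if d == -1:
            continue
        if d < best_d:
            best, best_d, ties = b, d, 1
        elif d == best_d:
            ties += 1
    if best is None or ties > 1:
        return None
    return best


# ---------------------------------------------------------------------------
# ATG scrubbing


def _overlaps(pos0: int, intervals) -> bool:
    """Does 0-based position ``pos0`` fall in any 1-based closed interval?"""
    p = pos0 + 1
    return any(s <= p <= e for s, e in intervals)


def _atg_positions(seq: str):
    return [i for i in range(len(seq) - 2) if seq[i : i + 3] == "ATG"]


def scrub_start_codons(seq: str, protected_intervals: Iterable = (), seed=None) -> str:
    """Remove every ATG triplet outside protected intervals.

    Each unprotected ATG is repaired by a single deterministic substitution
    (preferring the G, then the A, then the T) chosen so that no new ATG is
    created.  An ATG lying inside a protected interval (a splice-site motif
    such as the GTATGT 5'SS) is retained, and a stop codon is planted two
    codons downstream (starting 6 nt after the ATG, in its frame).  Length
    is always preserved.
    """
    protected = [tuple(iv[:2]) for iv in protected_intervals]
    s = list(seq)

    def creates_atg(lo, hi):
        w = "".join(s[max(0, lo - 2) : min(len(s), hi + 3)])
        off = max(0, lo - 2)
        return any(
            not _protected_atg(i + off) for i in range(len(w) - 2) if w[i : i + 3] == "ATG"
        )

    def _protected_atg(i):
        return all(_overlaps(i + k, protected) for k in range(3))

    guard = 0
    while True:
        guard += 1
        if guard > 10 * len(seq) + 10:
            raise DesignError("ATG scrubbing did not converge")
        hits = [i for i in _atg_positions("".join(s))]
        todo = None
        for i in hits:
            if all(_overlaps(i + k, protected) for k in range(3)):
                continue  # fully protected: the stop-codon exemption below
            todo = i
            break
        if todo is None:
            break
        i = todo
        fixed = False
        for k in (2, 0, 1):  # G first, then A, then T
            if _overlaps(i + k, protected):
                continue
            orig = s[i + k]
            for base in "TCAG":
                if base == orig or (k == 2 and base == "G"):
                    continue
                s[i + k] = base
                if s[i : i + 3] != ["A", "T", "G"] and not creates_atg(i + k, i + k):
                    fixed = True
                    break
                s[i + k] = orig
            if fixed:
                break
        if not fixed:
            raise DesignError(f"cannot scrub ATG at position {i + 1}")

    # stop-codon exemption: fully protected ATGs get a stop two codons downstream
    for i in _atg_positions("".join(s)):
        if not all(_overlaps(i + k, protected) for k in range(3)):
            continue
        lo = i + 6
        if lo + 3 > len(s):
            raise DesignError("no room for stop codon downstream of protected ATG")
        if "".join(s[lo : lo + 3]) in STOP_CODONS:
            continue
        placed = False
        for stop in STOP_CODONS:
            if any(_overlaps(p, protected) for p in range(lo, lo + 3)):
                break
            saved = s[lo : lo + 3]
            s[lo : lo + 3] = list(stop)
            if not creates_atg(lo, lo + 2):
                placed = True
                break
            s[lo : lo + 3] = saved
        if not placed:
            raise DesignError(
                "protected interval overlaps every repair position for the "
                "stop-codon exemption"
            )
    return "".join(s)


# ---------------------------------------------------------------------------
# sequence helpers


def random_background(
    rng: np.random.Generator, length: int = REGION_LEN, background_id: str = "bg0"
) -> str:
    """ATG-free random background region (synthetic stand-in for the
    gene-derived backgrounds of a real assay)."""
    seq = "".join(rng.choice(list(BASES), size=length))
    return scrub_start_codons(seq)


def _junction(seq: str, left_end: int, right_start: int, flank: int = JUNCTION_FLANK) -> str:
    """Reference junction across the boundary after 1-based ``left_end``:
    up to ``flank`` nt ending at left_end + up to ``flank`` nt starting at
    right_start (truncated at oligo ends)."""
    left = seq[max(0, left_end - flank) : left_end]
    right = seq[right_start - 1 : right_start - 1 + flank]
    return left + right


def _exon_intron_junctions(seq: str, start: int, end: int, prefix=""):
    return {
        f"{prefix}exon_intron_5": _junction(seq, start - 1, start),
        f"{prefix}intron_exon_3": _junction(seq, end, end + 1),
        f"{prefix}exon_exon": _junction(seq, start - 1, end + 1),
    }


# ---------------------------------------------------------------------------
# variant builders


def build_combinatorial_variant(
    features: DesignFeatures,
    background: str,
    barcode: str,
    variant_id: str = "comb_0",
    subset_label: str = "combinatorial",
) -> OligoVariant:
    """Place a synthetic intron on a background region.

    Geometry (1-based oligo coordinates, barcode = positions 1-12):
    the 5'SS occupies 18-23; the intron spans 18 .. 18+L-1; the 3'SS is the
    last 3 intron bases; the branch motif ends ``bs_to_3ss`` nt before the
    intron end (the distance counts from the first base after the motif
    through the final intron base); the U element sits immediately upstream
    of the 3'SS.
    """
    features.validate()
    if len(background) != REGION_LEN:
        raise DesignError("background must be 158 nt")
    L, D = features.intron_len, features.bs_to_3ss
    region_off = FIVE_SS_START - BARCODE_LEN - 1  # 0-based region index of intron start
    intron_end_r = region_off + L - 1
    if intron_end_r >= REGION_LEN:
        raise DesignError("intron extends past the variable region")
    region = list(background)

    def place(idx0, s):
        region[idx0 : idx0 + len(s)] = list(s)
        return (BARCODE_LEN + idx0 + 1, BARCODE_LEN + idx0 + len(s))  # oligo coords

    iv_5ss = place(region_off, features.five_ss)
    iv_3ss = place(intron_end_r - 2, features.three_ss)
    bs_end_r = intron_end_r - D  # 0-based index of last BS base
    iv_bs = place(bs_end_r - 6, features.branch)
    u = features.u_element
    iv_u = place(intron_end_r - 2 - len(u), u)
    if iv_bs[1] >= iv_u[0]:
        raise DesignError("branch site overlaps U element")

    oligo = barcode + "".join(region)
    protected = [iv_5ss, iv_bs, iv_u, iv_3ss]
    oligo = scrub_start_codons(oligo, protected)
    start, end = FIVE_SS_START, FIVE_SS_START + L - 1
    feats = asdict(features)
    feats["site_intervals"] = {
        "five_ss": iv_5ss,
        "branch": iv_bs,
        "u_element": iv_u,
        "three_ss": iv_3ss,
    }
    return OligoVariant(
        variant_id=variant_id,
        barcode=oligo[:BARCODE_LEN],
        variable_region=oligo[BARCODE_LEN:],
        subset_label=subset_label,
        features=feats,
        introns=[(start, end)],
        junctions=_exon_intron_junctions(oligo, start, end),
    )


def recover_design_features(variant: OligoVariant) -> DesignFeatures:
    """Re-parse a combinatorial variant's sequence back into the
    DesignFeatures used to build it (round-trip identity check)."""
    seq = variant.sequence
    (start, end) = variant.introns[0]
    L = end - start + 1
    f = variant.features
    D = f["bs_to_3ss"]
    bs_end = end - D
    u_len = len(f["u_element"])
    return DesignFeatures(
        five_ss=seq[start - 1 : start + 5],
        branch=seq[bs_end - 7 : bs_end],
        three_ss=seq[end - 3 : end],
        intron_len=L,
        bs_to_3ss=D,
        u_element=seq[end - 3 - u_len : end - 3],
        background_id=f["background_id"],
    )


def insert_natural_intron(
    intron_seq: str,
    flank5: str,
    flank3: str,
    background: str,
    barcode: str,
    variant_id: str = "nat_0",
    subset_label: str = "natural",
    metadata: dict | None = None,
    protect_intron: bool = False,
) -> OligoVariant:
    """Insert a full intron with 5-nt exonic flanks at the 5' end of the
    variable region; the remainder of the background fills the 3' end."""
    if len(intron_seq) > REGION_LEN - 10:
        raise DesignError(f"intron longer than {REGION_LEN - 10} nt cannot fit the region")
    if len(flank5) != 5 or len(flank3) != 5:
        raise DesignError("flanks must be 5 nt each")
    head = flank5 + intron_seq + flank3
    region = head + background[len(head) :]
    if len(region) != REGION_LEN:
        raise DesignError("background shorter than the variable region")
    start = BARCODE_LEN + len(flank5) + 1  # == 18
    end = start + len(intron_seq) - 1
    oligo = barcode + region
    if protect_intron:
        protected = [(start, end)]
    else:
        protected = [(start, start + 5), (end - 2, end)]  # 5'SS and 3'SS motifs
    oligo = scrub_start_codons(oligo, protected)
    feats = dict(metadata or {})
    feats.setdefault("intron_len", len(intron_seq))
    feats.setdefault("background_id", "bg0")
    return OligoVariant(
        variant_id=variant_id,
        barcode=oligo[:BARCODE_LEN],
        variable_region=oligo[BARCODE_LEN:],
        subset_label=subset_label,
        features=feats,
        introns=[(start, end)],
        junctions=_exon_intron_junctions(oligo, start, end),
    )


def build_two_intron_variant(
    intron_a: str,
    intron_b: str,
    background: str,
    barcode: str,
    variant_id: str = "ti_0",
    min_middle_exon: int = 10,
    exon1_len: int = 5,
    exon3_len: int = 20,
    metadata: dict | None = None,
) -> OligoVariant:
    """Two-intron design: exon1 - intronA - exon2 - intronB - exon3.

    exon1 is a short 5-nt lead (the natural-intron flank convention);
    exon3 is a 20-nt tail so every junction reference keeps a full
    discriminative exonic flank (a flank much shorter than the junction
    window sits at the positive-call boundary for unspliced reads).  The
    middle exon is filled from the background and varies in length with
    the two introns.  All 8 reference junctions are generated.
    """
    La, Lb = len(intron_a), len(intron_b)
    if La >= 76 or Lb >= 76:
        raise DesignError("two-intron designs use introns shorter than 76 nt")
    e2_len = REGION_LEN - exon1_len - exon3_len - La - Lb
    if e2_len < min_middle_exon:
        raise DesignError("introns too long to fit with a middle exon")
    exon1 = background[:exon1_len]
    exon2 = background[exon1_len : exon1_len + e2_len]
    exon3 = background[exon1_len + e2_len : exon1_len + e2_len + exon3_len]
    region = exon1 + intron_a + exon2 + intron_b + exon3
    a_start = BARCODE_LEN + exon1_len + 1
    a_end = a_start + La - 1
    b_start = a_end + e2_len + 1
    b_end = b_start + Lb - 1
    oligo = barcode + region
    protected = [
        (a_start, a_start + 5),
        (a_end - 2, a_end),
        (b_start, b_start + 5),
        (b_end - 2, b_end),
    ]
    oligo = scrub_start_codons(oligo, protected)

    junctions = {
        "exon1_intron1": _junction(oligo, a_start - 1, a_start),
        "intron1_exon2": _junction(oligo, a_end, a_end + 1),
        "exon2_intron2": _junction(oligo, b_start - 1, b_start),
        "intron2_exon3": _junction(oligo, b_end, b_end + 1),
        "exon1_exon2": _junction(oligo, a_start - 1, a_end + 1),
        "exon2_exon3": _junction(oligo, b_start - 1, b_end + 1),
    }
    # junctions of doubly-spliced products, built on spliced sequences
    skip = oligo[: a_start - 1] + oligo[b_end:]  # exon1+exon3 (both introns+exon2 out)
    junctions["exon1_exon3"] = _junction(skip, a_start - 1, a_start)
    both = oligo[: a_start - 1] + oligo[a_end : b_start - 1] + oligo[b_end:]
    # window spanning both splice boundaries of the fully spliced product
    j1 = a_start - 1  # last exon1 base in 'both' coordinates
    j2 = j1 + e2_len  # last exon2 base
    junctions["exon1_exon2_exon3"] = both[max(0, j1 - JUNCTION_FLANK) : j2 + JUNCTION_FLANK]

    feats = dict(metadata or {})
    feats.setdefault("intron1_len", La)
    feats.setdefault("intron2_len", Lb)
    feats.setdefault("middle_exon_len", e2_len)
    feats.setdefault("exon1_len", exon1_len)
    feats.setdefault("exon3_len", exon3_len)
    feats.setdefault("background_id", "bg0")
    return OligoVariant(
        variant_id=variant_id,
        barcode=oligo[:BARCODE_LEN],
        variable_region=oligo[BARCODE_LEN:],
        subset_label="two_intron",
        features=feats,
        introns=[(a_start, a_end), (b_start, b_end)],
        junctions=junctions,
    )


def mutate_for_structure(
    variant: OligoVariant,
    site: str,
    fold_engine=None,
    max_tries: int = 2000,
    seed: int | None = None,
    window: int = 16,
    max_mutations: int = 8,
    barcode: str | None = None,
) -> OligoVariant:
    """Mutate positions around a splice site until the whole site is
    predicted base-paired within a local stem-loop.

    ``site`` is one of ``5ss``, ``bs``, ``3ss``.  Mutations never touch any
    splice-site motif.  The fold engine defaults to the package's Nussinov
    maximum-pairing engine; it must expose ``pairing_mask(seq) -> bool
    array``.
    """
    from . import structure

    if fold_engine is None:
        fold_engine = structure.fold_window
    key = {"5ss": "five_ss", "bs": "branch", "3ss": "three_ss"}[site]
    ivs = variant.features.get("site_intervals")
    if not ivs:
        raise DesignError("structure mutants require a combinatorial variant")
    s, e = ivs[key]
    site_idx = set(range(s - 1, e))
    forbidden = set()
    for a, b in ivs.values():
        forbidden.update(range(a - 1, b))
    seq = (barcode or variant.barcode) + variant.variable_region
    lo = max(0, s - 1 - window)
    hi = min(len(seq), e + window)
    mutable = [i for i in range(lo, hi) if i not in forbidden]
    site_seq = seq[s - 1 : e]
    rc = site_seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    # contiguous mutable runs long enough to host a complementary patch,
    # at least a hairpin loop away from the site
    runs = []
    run = []
    for i in mutable:
        if run and i != run[-1] + 1:
            runs.append(run)
            run = []
        run.append(i)
    if run:
        runs.append(run)
    patch_starts = [
        r[j]
        for r in runs
        for j in range(len(r) - len(rc) + 1)
        if r[j] + len(rc) <= s - 1 - 3 or r[j] >= e + 3
    ]
    rng = np.random.default_rng(seed)
    for t in range(max_tries):
        cand = list(seq)
        if patch_starts and t % 2 == 0:
            # seed a complementary patch, then add random noise mutations
            p0 = int(rng.choice(patch_starts))
            cand[p0 : p0 + len(rc)] = list(rc)
            extra = rng.choice(mutable, size=int(rng.integers(0, 3)), replace=False)
            for p in extra:
                cand[p] = rng.choice([b for b in BASES if b != cand[p]])
            pos = [i for i in mutable if cand[i] != seq[i]]
        else:
            k = int(rng.integers(1, max_mutations + 1))
            pos = rng.choice(mutable, size=min(k, len(mutable)), replace=False)
            for p in pos:
                cand[p] = rng.choice([b for b in BASES if b != seq[p]])
        cand_seq = "".join(cand)
        w0, w1 = max(0, lo - 2), hi + 2
        preexisting = set(_atg_positions(seq[w0:w1]))
        if set(_atg_positions(cand_seq[w0:w1])) - preexisting:
            continue  # a mutation created a new start codon

        fold = fold_engine(cand_seq[lo:hi])
        mask = fold.pairing_mask
        if all(mask[i - lo] for i in site_idx):
            muts = sorted(int(p) + 1 for p in pos)
            feats = dict(variant.features)
            feats["structure_site"] = site
            feats["structure_mutations"] = muts
            start, end = variant.introns[0]
            oligo = cand_seq
            return OligoVariant(
                variant_id=variant.variant_id + f"_struct_{site}",
                barcode=oligo[:BARCODE_LEN],
                variable_region=oligo[BARCODE_LEN:],
                subset_label="mutated",
                features=feats,
                introns=list(variant.introns),
                junctions=_exon_intron_junctions(oligo, start, end),
            )
    raise DesignError(
        f"no accepted structure mutant for site {site} within {max_tries} tries "
        f"(window={window}, max_mutations={max_mutations})"
    )


def mutate_splice_sites(
    variant: OligoVariant,
    sites: Sequence[str],
    rng: np.random.Generator,
    barcode: str | None = None,
    variant_id: str | None = None,
) -> OligoVariant:
    """Random point mutation inside each named site motif (splice-site
    mutant subset).  A fresh ``barcode`` may be supplied; junctions are
    rebuilt on the final sequence."""
    ivs = variant.features.get("site_intervals")
    if not ivs:
        raise DesignError("site mutants require a combinatorial variant")
    seq = list((barcode or variant.barcode) + variant.variable_region)
    mutated = {}
    for site in sites:
        a, b = ivs[site]
        p = int(rng.integers(a - 1, b))
        old = seq[p]
        seq[p] = rng.choice([x for x in BASES if x != old])
        mutated[site] = p + 1
    oligo = "".join(seq)
    if _atg_positions(oligo):
        oligo = scrub_start_codons(oligo, list(ivs.values()))
    start, end = variant.introns[0]
    feats = dict(variant.features)
    feats["mutated_sites"] = mutated
    feats["parent_variant"] = variant.variant_id
    return OligoVariant(
        variant_id=variant_id or (variant.variant_id + "_mut_" + "".join(s[0] for s in sites)),
        barcode=oligo[:BARCODE_LEN],
        variable_region=oligo[BARCODE_LEN:],
        subset_label="mutated",
        features=feats,
        introns=[(start, end)],
        junctions=_exon_intron_junctions(oligo, start, end),
    )


# ---------------------------------------------------------------------------
# synthetic "natural" introns and whole-library assembly


def make_synthetic_intron(
    length: int,
    bs_to_3ss: int,
    rng: np.random.Generator,
    catalog: SpliceSiteCatalog | None = None,
    u_element: str = "TTTAA",
) -> str:
    """Consensus-site intron with random ATG-free filler, used as the
    synthetic stand-in for a natural intron sequence."""
    catalog = catalog or SpliceSiteCatalog()
    c = catalog.consensus
    filler_len = length - 6 - 7 - bs_to_3ss
    if filler_len < 5 or bs_to_3ss < len(u_element) + 3:
        # < 5 leaves no room for the stop-codon exemption of the 5'SS ATG
        raise DesignError("intron geometry does not fit")
    fill1 = "".join(rng.choice(list(BASES), size=filler_len))
    pad = "".join(rng.choice(list(BASES), size=bs_to_3ss - len(u_element) - 3))
    intron = c["five_ss"] + fill1 + c["branch"] + pad + u_element + c["three_ss"]
    intron = scrub_start_codons(
        intron, [(1, 6), (7 + filler_len, 13 + filler_len), (length - 2, length)]
    )
    assert len(intron) == length
    return intron


@dataclass
class LibraryConfig:
    """Subset sizes and options for :func:`design_library`.

    Defaults are a desk-scale library that preserves the full subset
    structure of the assay; the combinatorial geometry grid (lengths 73-137,
    distances 20-50) is always the full one.
    """

    n_combinatorial: int = 120
    n_negative_controls: int = 30
    n_natural: int = 30
    n_mutated: int = 30
    n_structure: int = 0  # structure search is expensive; opt in
    two_intron_pool: int = 6  # introns in the pairing pool (pool**2 variants)
    nn_instantiations: int = 1  # concrete draws per degenerate BS template
    intron_lengths: tuple = (73, 89, 105, 121, 137)
    bs_to_3ss_lengths: tuple = (20, 30, 40, 50)
    n_backgrounds: int = 1


def _instantiate_branch(branch: str, rng) -> str:
    return "".join(rng.choice(list(BASES)) if c == "N" else c for c in branch)


def design_library(
    config: LibraryConfig | None = None,
    seed: int | None = None,
    catalog: SpliceSiteCatalog | None = None,
) -> list:
    """Assemble a library with all five subsets; deterministic for a seed."""
    config = config or LibraryConfig()
    rng = np.random.default_rng(seed)
    catalog = catalog or SpliceSiteCatalog()
    if not catalog.control_sites:
        catalog.make_control_sites(rng)
    backgrounds = {
        f"bg{i}": random_background(rng, background_id=f"bg{i}")
        for i in range(config.n_backgrounds)
    }
    bg_ids = list(backgrounds)

    # enumerate the combinatorial grid, instantiating degenerate templates
    branches = []
    for b in catalog.branch_sites:
        if "N" in b:
            branches += [_instantiate_branch(b, rng) for _ in range(config.nn_instantiations)]
        else:
            branches.append(b)
    grid = list(
        itertools.product(
            catalog.five_prime_sites,
            branches,
            catalog.three_prime_sites,
            config.intron_lengths,
            config.bs_to_3ss_lengths,
            catalog.u_elements,
        )
    )
    rng.shuffle(grid)

    n_two_intron = config.two_intron_pool**2
    total = (
        config.n_combinatorial
        + config.n_negative_controls
        + config.n_natural
        + config.n_mutated
        + config.n_structure
        + n_two_intron
    )
    barcodes = iter(generate_barcodes(total, seed=int(rng.integers(2**31))))
    variants: list[OligoVariant] = []

    for i in range(config.n_combinatorial):
        f5, bs, t3, L, D, u = grid[i % len(grid)]
        feats = DesignFeatures(f5, bs, t3, L, D, u, background_id=bg_ids[i % len(bg_ids)])
        variants.append(
            build_combinatorial_variant(
                feats, backgrounds[feats.background_id], next(barcodes), f"comb_{i:05d}"
            )
        )

    cs = catalog.control_sites
    for i in range(config.n_negative_controls):
        _, _, _, L, D, u = grid[i % len(grid)]
        feats = DesignFeatures(
            cs["five_ss"], cs["branch"], cs["three_ss"], L, D, u, background_id=bg_ids[0]
        )
        variants.append(
            build_combinatorial_variant(
                feats,
                backgrounds[bg_ids[0]],
                next(barcodes),
                f"neg_{i:05d}",
                subset_label="negative_control",
            )
        )

    for i in range(config.n_natural):
        D = int(rng.choice(config.bs_to_3ss_lengths))
        # keep >=5 nt between 5'SS and branch motif (room for the
        # stop-codon exemption inside consensus 5'SS introns)
        L = int(rng.integers(max(60, 18 + D), 149))
        intron = make_synthetic_intron(L, D, rng, catalog)
        flank5 = "".join(rng.choice(list(BASES), size=5))
        flank3 = "".join(rng.choice(list(BASES), size=5))
        variants.append(
            insert_natural_intron(
                intron,
                flank5,
                flank3,
                backgrounds[bg_ids[0]],
                next(barcodes),
                f"nat_{i:05d}",
                metadata={
                    "species": f"sp{int(rng.integers(11))}",
                    "bs_to_3ss": D,
                    "background_id": bg_ids[0],
                },
            )
        )

    comb_pool = [v for v in variants if v.subset_label == "combinatorial"]
    for i in range(config.n_mutated):
        base = comb_pool[i % len(comb_pool)]
        sites = [["five_ss"], ["branch"], ["three_ss"], ["five_ss", "branch"]][i % 4]
        variants.append(
            mutate_splice_sites(
                base, sites, rng, barcode=next(barcodes), variant_id=f"mut_{i:05d}"
            )
        )

    for i in range(config.n_structure):
        base = comb_pool[i % len(comb_pool)]
        site = ["5ss", "bs", "3ss"][i % 3]
        v = mutate_for_structure(
            base, site, seed=int(rng.integers(2**31)), barcode=next(barcodes)
        )
        v.variant_id = f"struct_{i:05d}"
        variants.append(v)

    pool = [
        make_synthetic_intron(int(rng.integers(45, 57)), 20, rng, catalog)
        for _ in range(config.two_intron_pool)
    ]
    for i, (a, b) in enumerate(itertools.product(pool, repeat=2)):
        variants.append(
            build_two_intron_variant(
                a, b, backgrounds[bg_ids[0]], next(barcodes), f"ti_{i:05d}"
            )
        )
    return variants


# ---------------------------------------------------------------------------
# manifest I/O


def variants_to_manifest(variants: Sequence[OligoVariant]) -> pd.DataFrame:
    rows = []
    for v in variants:
        rows.append(
            {
                "variant_id": v.variant_id,
                "barcode": v.barcode,
                "variable_region": v.variable_region,
                "subset_label": v.subset_label,
                "introns": json.dumps(v.introns),
                "features": json.dumps(v.features),
                "junctions": json.dumps(v.junctions),
            }
        )
    return pd.DataFrame(rows)


def variants_from_manifest(df: pd.DataFrame) -> list:
    out = []
    for r in df.itertuples():
        out.append(
            OligoVariant(
                variant_id=r.variant_id,
                barcode=r.barcode,
                variable_region=r.variable_region,
                subset_label=r.subset_label,
                features=json.loads(r.features),
                introns=[tuple(x) for x in json.loads(r.introns)],
                junctions=json.loads(r.junctions),
            )
        )
    return out


def write_manifest(variants, tsv_path, fasta_path=None):
    df = variants_to_manifest(variants)
    df.to_csv(tsv_path, sep="\t", index=False)
    if fasta_path:
        with open(fasta_path, "w") as fh:
            for v in variants:
                fh.write(f">{v.variant_id}\n{v.sequence}\n")
    return df


def read_manifest(tsv_path) -> list:
    return variants_from_manifest(pd.read_csv(tsv_path, sep="\t"))
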