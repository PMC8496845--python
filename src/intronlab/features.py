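"""Feature extraction for the splicing-efficiency model.

Every single-intron variant is summarized by a fixed schema of 39 features
covering: the three splice-site sequences and the U element (categorical),
the background identity, intron geometry (length, branch-to-3'SS and
5'SS-to-branch distances, position), nucleotide composition of the intron
and its sub-regions, the U/Y tract in the 20-nt window upstream of the
3'SS, predicted local secondary structure (Nussinov dG proxy) in windows
at each splice site and across the intron, and acceptor-motif context
(counts and positions of HAG triplets that could act as alternative 3'
splice sites).

The schema is frozen in :data:`FEATURE_SCHEMA`; extraction is a pure
function of the variant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import structure
from .design import OligoVariant
from .stats import c_fraction_of_y, three_ss_upstream_window, u_content, y_content

__all__ = ["FEATURE_SCHEMA", "CATEGORICAL_FEATURES", "extract_features", "feature_table"]

CATEGORICAL_FEATURES = [
    "five_ss_seq",
    "branch_seq",
    "three_ss_seq",
    "u_element_seq",
    "background_id",
]

NUMERIC_FEATURES = [
    "intron_length",
    "bs_to_3ss_distance",
    "five_ss_to_bs_distance",
    "intron_start_position",
    "downstream_exon_length",
    "intron_gc_content",
    "intron_a_content",
    "intron_u_content",
    "bs_to_3ss_gc_content",
    "bs_to_3ss_u_content",
    "upstream_exon_gc_content",
    "downstream_exon_gc_content",
    "barcode_gc_content",
    "u_content_20nt_upstream_3ss",
    "y_content_20nt_upstream_3ss",
    "c_fraction_of_y_20nt",
    "max_u_run_20nt",
    "u_element_length",
    "five_ss_is_consensus",
    "branch_is_consensus",
    "three_ss_is_yag",
    "dg_five_ss_window",
    "dg_branch_window",
    "dg_three_ss_window",
    "dg_three_ss_window30",
    "dg_intron_start30",
    "dg_intron_end30",
    "five_ss_paired_fraction",
    "branch_paired_fraction",
    "three_ss_paired_fraction",
    "n_hag_intron",
    "n_hag_bs_to_3ss",
    "dist_bs_to_first_hag",
    "n_hag_downstream_exon_30",
]

FEATURE_SCHEMA = CATEGORICAL_FEATURES + NUMERIC_FEATURES
assert len(FEATURE_SCHEMA) == 39


def _gc(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


def _max_run(seq: str, char: str) -> int:
    best = cur = 0
    for c in seq:
        cur = cur + 1 if c == char else 0
        best = max(best, cur)
    return best


def _hag_positions(seq: str):
    return [
        i for i in range(len(seq) - 2)
        if seq[i] in "ACT" and seq[i + 1 : i + 3] == "AG"
    ]


def _window(seq: str, center_start: int, center_end: int, pad: int) -> str:
    """Window of ``pad`` nt on each side of a 1-based closed interval."""
    return seq[max(0, center_start - 1 - pad) : min(len(seq), center_end + pad)]


def extract_features(variant: OligoVariant, fold_engine: str = "nussinov") -> dict:
    """Deterministic 39-entry feature vector for a single-intron variant."""
    if not variant.introns or variant.subset_label == "two_intron":
        raise ValueError("feature extraction requires a single-intron variant")
    seq = variant.sequence
    start, end = variant.introns[0]
    intron = seq[start - 1 : end]
    L = len(intron)
    f = variant.features
    five_ss = intron[:6]
    three_ss = intron[-3:]
    D = int(f.get("bs_to_3ss", 0)) or max(L - 13, 0)
    bs_end = end - D
    branch = seq[bs_end - 7 : bs_end] if bs_end - 7 >= start - 1 else intron[6:13]
    u_elem = str(f.get("u_element", ""))
    tract = three_ss_upstream_window(variant, 20)
    bs3 = seq[bs_end : end]  # branch end (exclusive) .. intron end
    upstream_exon = seq[:start - 1]
    downstream_exon = seq[end:]

    def dg(window_seq: str) -> float:
        return structure.fold_window(window_seq, engine=fold_engine).score

    def paired_fraction(center_start, center_end, pad=15) -> float:
        w = _window(seq, center_start, center_end, pad)
        off = center_start - 1 - max(0, center_start - 1 - pad)
        mask = structure.fold_window(w, engine=fold_engine).pairing_mask
        span = mask[off : off + (center_end - center_start + 1)]
        return float(span.mean()) if span.size else 0.0

    hag_in_intron = _hag_positions(intron)
    hag_in_bs3 = _hag_positions(bs3)
    # distance (nt) from the branch end to the first downstream HAG start
    dist_first_hag = float(hag_in_bs3[0] + 1) if hag_in_bs3 else float(len(bs3) + 1)

    return {
        "five_ss_seq": five_ss,
        "branch_seq": branch,
        "three_ss_seq": three_ss,
        "u_element_seq": u_elem or "none",
        "background_id": str(f.get("background_id", "bg0")),
        "intron_length": float(L),
        "bs_to_3ss_distance": float(D),
        "five_ss_to_bs_distance": float(max(bs_end - 7 - (start - 1) - 6, 0)),
        "intron_start_position": float(start),
        "downstream_exon_length": float(len(downstream_exon)),
        "intron_gc_content": _gc(intron),
        "intron_a_content": intron.count("A") / L,
        "intron_u_content": u_content(intron),
        "bs_to_3ss_gc_content": _gc(bs3),
        "bs_to_3ss_u_content": u_content(bs3) if bs3 else 0.0,
        "upstream_exon_gc_content": _gc(upstream_exon),
        "downstream_exon_gc_content": _gc(downstream_exon),
        "barcode_gc_content": _gc(variant.barcode),
        "u_content_20nt_upstream_3ss": u_content(tract),
        "y_content_20nt_upstream_3ss": y_content(tract),
        "c_fraction_of_y_20nt": c_fraction_of_y(tract),
        "max_u_run_20nt": float(_max_run(tract, "T")),
        "u_element_length": float(len(u_elem)),
        "five_ss_is_consensus": float(five_ss == "GTATGT"),
        "branch_is_consensus": float(branch == "TACTAAC"),
        "three_ss_is_yag": float(three_ss in ("CAG", "TAG")),
        "dg_five_ss_window": dg(_window(seq, start, start + 5, 12)),
        "dg_branch_window": dg(_window(seq, bs_end - 6, bs_end, 12)),
        "dg_three_ss_window": dg(_window(seq, end - 2, end, 12)),
        "dg_three_ss_window30": dg(_window(seq, end - 2, end, 15)[:30]),
        "dg_intron_start30": dg(intron[:30]),
        "dg_intron_end30": dg(intron[-30:]),
        "five_ss_paired_fraction": paired_fraction(start, start + 5),
        "branch_paired_fraction": paired_fraction(bs_end - 6, bs_end),
        "three_ss_paired_fraction": paired_fraction(end - 2, end),
        "n_hag_intron": float(len(hag_in_intron)),
        "n_hag_bs_to_3ss": float(len(hag_in_bs3)),
        "dist_bs_to_first_hag": dist_first_hag,
        "n_hag_downstream_exon_30": float(len(_hag_positions(downstream_exon[:30]))),
    }


def feature_table(variants, fold_engine: str = "nussinov") -> pd.DataFrame:
    """Feature matrix (one row per variant, schema order) with categorical
    dtype on the categorical columns."""
    rows = []
    ids = []
    for v in variants:
        rows.append(extract_features(v, fold_engine))
        ids.append(v.variant_id)
    df = pd.DataFrame(rows, index=pd.Index(ids, name="variant_id"))
    df = df[FEATURE_SCHEMA]
    for c in CATEGORICAL_FEATURES:
        df[c] = df[c].astype("category")
    assert not df.isna().any().any()
    return df
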