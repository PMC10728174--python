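"""Delta profiles, metagenes, per-locus summaries and translocation summaries.

Background removal follows the damaged-undamaged convention: the
per-nucleotide mutation rate of the undamaged (-DSB) sample is subtracted
from the damaged (+DSB) sample at every position and for every mutation
type, which cancels genomic SNVs and PCR/sequencing error.  Treatment
effects are the second-order delta: (treatment +DSB - treatment -DSB) -
(control +DSB - control -DSB).  Deltas may be negative and are never
floored.

"Per DSB" totals are sums of per-position percent rates over the profiled
cut-relative window; metagene profiles average loci of a group (HR, NHEJ,
UNCUT) at each signed distance from the cut, unweighted by depth.
"""

from __future__ import annotations

from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .amplicon_catalog import PrimerPool
from .errors import DomainError, PoolValidationError
from .mutation_caller import MProfile, SUB_DIRECTIONS, annotations_to_frame
from .translocapture import TranslocationMatrix

RateFrame = pd.DataFrame  # per-(locus_id, pos) percent-rate table

_RATE_COLUMNS = (
    [f"sub_{c}" for c in SUB_DIRECTIONS]
    + ["sub_total", "ins_rate", "del_cov_rate", "del_small_rate", "del_mid_rate", "del_large_rate"]
)

#: reverse-complement collapse of the 12 directional changes onto the
#: 6 pyrimidine-reference classes (G>A is read as C>T on the other strand)
SIGNATURE_COLLAPSE = {
    "CtoA": "C>A", "GtoT": "C>A",
    "CtoG": "C>G", "GtoC": "C>G",
    "CtoT": "C>T", "GtoA": "C>T",
    "TtoA": "T>A", "AtoT": "T>A",
    "TtoC": "T>C", "AtoG": "T>C",
    "TtoG": "T>G", "AtoC": "T>G",
}
SIGNATURE_CLASSES = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]


def _as_rates(profile: Union[MProfile, RateFrame], min_depth: int = 100) -> RateFrame:
    if isinstance(profile, MProfile):
        return profile.rates(min_depth)
    return profile


def delta_profiles(
    a: Union[MProfile, RateFrame],
    b: Union[MProfile, RateFrame],
    min_depth: int = 100,
) -> RateFrame:
    """Per-position, per-mutation-type signed rate difference a - b.

    Both profiles must share the position grid; positions missing (NaN,
    i.e. below min_depth) on either side stay missing in the output.
    """
    ra, rb = _as_rates(a, min_depth), _as_rates(b, min_depth)
    if not ra.index.equals(rb.index):
        raise DomainError("delta_profiles: position grids differ")
    cols = [c for c in _RATE_COLUMNS if c in ra.columns and c in rb.columns]
    out = ra[[c for c in ("ref_base", "rel_pos") if c in ra.columns]].copy()
    out["depth_a"] = ra["depth"]
    out["depth_b"] = rb["depth"]
    for c in cols:
        out[c] = ra[c] - rb[c]
    return out


def chained_treatment_delta(
    treat_plus, treat_minus, ctrl_plus, ctrl_minus, min_depth: int = 100
) -> RateFrame:
    """(treat+ - treat-) - (ctrl+ - ctrl-), per nucleotide and mutation type."""
    d_treat = delta_profiles(treat_plus, treat_minus, min_depth)
    d_ctrl = delta_profiles(ctrl_plus, ctrl_minus, min_depth)
    cols = [c for c in _RATE_COLUMNS if c in d_treat.columns]
    out = d_treat[[c for c in ("ref_base", "rel_pos") if c in d_treat.columns]].copy()
    for c in cols:
        out[c] = d_treat[c] - d_ctrl[c]
    return out


def metagene_profile(
    rates: RateFrame,
    pool: PrimerPool,
    group: Union[str, Iterable[str]],
    window: int = 100,
    column: str = "sub_total",
) -> pd.DataFrame:
    """Cut-aligned average of one rate column across a group of loci.

    ``group`` is a repair class ("HR", "NHEJ") or an iterable of locus
    ids; every locus must have a cut site and the window must fit inside
    each amplicon.  Returns a DataFrame indexed by rel_pos (-W..+W) with
    one column per locus plus the unweighted ``mean`` row average.
    """
    if isinstance(group, str):
        loci = pool.by_class(group)
        if not loci:
            raise DomainError(f"no loci in group {group!r}")
    else:
        loci = [pool[lid] for lid in group]
    rel = np.arange(-window, window + 1)
    per_locus = {}
    for locus in loci:
        if not locus.is_cut:
            raise DomainError(
                f"{locus.locus_id}: UNCUT locus cannot be aligned at a cut site"
            )
        if locus.cut_offset - window < 0 or locus.cut_offset + window >= len(locus.ref_seq):
            raise DomainError(
                f"{locus.locus_id}: window {window} exceeds amplicon bounds"
            )
        sub = rates.loc[locus.locus_id]
        per_locus[locus.locus_id] = (
            sub[column].reindex(locus.cut_offset + rel).to_numpy()
        )
    df = pd.DataFrame(per_locus, index=pd.Index(rel, name="rel_pos"))
    df["mean"] = df[[l.locus_id for l in loci]].mean(axis=1)
    return df


def collapse_signature(sub_rates: pd.Series) -> pd.Series:
    """Collapse 12 directional substitution rates onto the 6 pyrimidine classes."""
    out = {c: 0.0 for c in SIGNATURE_CLASSES}
    for direction, cls in SIGNATURE_COLLAPSE.items():
        col = f"sub_{direction}"
        if col in sub_rates.index and pd.notna(sub_rates[col]):
            out[cls] += float(sub_rates[col])
    return pd.Series(out)


def locus_summary(
    profile: Union[MProfile, RateFrame],
    annotations: list,
    pool: PrimerPool,
    window: int = 100,
    min_depth: int = 100,
    adjacency_bp: int = 10,
    aggregate: str = "sum",
) -> pd.DataFrame:
    """Per-locus totals over the profiled window, in percent per DSB.

    For cut loci the window is the +/-``window`` bp around the cut; uncut
    controls use their whole primer-free interior.  Totals are sums of
    per-position percent rates (``aggregate="mean"`` gives per-position
    means instead).  Deletion events are split by size class and
    adjacency; the MMEJ rate counts large deletions with junction
    microhomology >= 2.  The 6-class substitution signature is the
    reverse-complement collapse of the 12 directional rates.
    """
    if aggregate not in ("sum", "mean"):
        raise DomainError(f"aggregate must be 'sum' or 'mean', got {aggregate!r}")
    rates = _as_rates(profile, min_depth)
    ann = annotations_to_frame(annotations) if isinstance(annotations, list) else annotations
    rows = []
    for locus_id in rates.index.get_level_values("locus_id").unique():
        if locus_id not in pool:
            raise PoolValidationError(f"unknown locus {locus_id!r} in profile")
        locus = pool[locus_id]
        sub = rates.loc[locus_id]
        if locus.is_cut:
            lo, hi = locus.cut_offset - window, locus.cut_offset + window
        else:
            lo, hi = locus.interior()
            hi -= 1
        win = sub.loc[lo:hi]
        agg = win.sum(skipna=True) if aggregate == "sum" else win.mean(skipna=True)
        depth = win["depth"]
        mean_depth = float(depth.mean()) if len(depth) else 0.0

        lann = ann[ann["locus_id"] == locus_id] if len(ann) else ann
        n_reads = mean_depth if mean_depth > 0 else np.nan

        def _event_pct(mask) -> float:
            if not len(lann) or not np.isfinite(n_reads):
                return 0.0
            return 100.0 * float(lann.loc[mask, "count"].sum()) / n_reads

        row = {
            "locus_id": locus_id,
            "repair_class": locus.repair_class,
            "mean_depth": mean_depth,
            "sub_total": float(agg["sub_total"]),
            "ins_total": float(agg["ins_rate"]),
            "del_cov_total": float(agg["del_cov_rate"]),
            "del_small_total": float(agg["del_small_rate"]),
            "del_mid_total": float(agg["del_mid_rate"]),
            "del_large_total": float(agg["del_large_rate"]),
        }
        if len(lann):
            row["del_adjacent_pct"] = _event_pct(lann["adjacency"] == "adjacent")
            row["del_distant_pct"] = _event_pct(lann["adjacency"] == "distant")
            row["mmej_pct"] = _event_pct(lann["mmej"])
            row["slippage_pct"] = _event_pct(lann["slippage"])
        else:
            row.update(del_adjacent_pct=0.0, del_distant_pct=0.0, mmej_pct=0.0, slippage_pct=0.0)
        sig = collapse_signature(agg[[f"sub_{c}" for c in SUB_DIRECTIONS]])
        for cls in SIGNATURE_CLASSES:
            row[f"sig_{cls}"] = sig[cls]
        rows.append(row)
    return pd.DataFrame(rows).set_index("locus_id")


def translocation_summary(matrix: TranslocationMatrix, pool: PrimerPool) -> dict:
    """Mean unordered-pair translocation rate within and between repair classes.

    Returns ``{"class_pairs": DataFrame, "pair_map": DataFrame}`` where
    class pairs are HR-HR, NHEJ-NHEJ, HR-NHEJ and UNCUT-any and the pair
    map is the full per-unordered-pair rate table for heatmap export.
    """
    unknown = set(matrix.locus_ids) - set(pool.locus_ids)
    if unknown:
        raise PoolValidationError(f"matrix loci not in pool: {sorted(unknown)}")
    pair_map = matrix.unordered_pair_rates()
    cls = {loc.locus_id: loc.repair_class for loc in pool}
    pair_map["class_a"] = pair_map["locus_a"].map(cls)
    pair_map["class_b"] = pair_map["locus_b"].map(cls)

    def _pair_class(row) -> str:
        pair = {row["class_a"], row["class_b"]}
        if "UNCUT" in pair:
            return "UNCUT-any"
        if pair == {"HR"}:
            return "HR-HR"
        if pair == {"NHEJ"}:
            return "NHEJ-NHEJ"
        return "HR-NHEJ"

    pair_map["class_pair"] = pair_map.apply(_pair_class, axis=1)
    class_pairs = (
        pair_map.groupby("class_pair")["rate"]
        .agg(["mean", "sum", "count"])
        .reindex(["HR-HR", "NHEJ-NHEJ", "HR-NHEJ", "UNCUT-any"])
        .fillna(0.0)
    )
    return {"class_pairs": class_pairs, "pair_map": pair_map}
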