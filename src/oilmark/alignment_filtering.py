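"""Cross-sample feature alignment and the flag/frequency/blank filters.

Alignment groups molecular features from many runs into consensus compounds
using combined relative + absolute tolerances (defaults: 0.1 % + 0.15 min on
RT, 5 ppm + 2.0 mDa on m/z).  The algorithm is greedy seeded clustering:
features are pre-sorted by descending height (ties: m/z, RT, input order);
each unassigned feature seeds a consensus compound and absorbs every
unassigned feature whose own tolerance window overlaps the seed's (i.e.
|d| <= hw_seed + hw_feature on both axes), at most one per sample (ties
broken by smallest |dm/z|, then |dRT|, then input order).  A second
pass recentres: features are re-assigned to consensus compounds (strongest
first) using windows around the intensity-weighted consensus reference
rather than around the original seed, which heals the boundary splits a
single seed-centred pass produces when a run's RT jitter straddles the
window edge.  The pre-sort makes the result invariant to the order samples
are supplied in; greediness makes it deterministic and near-linear, which is
the standard trade-off in metabolomics preprocessing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import Sample, ToleranceWindows, check_unique_ids

log = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Aligned consensus compounds x samples abundance table.

    ``abundance[i, j]`` is the peak height of consensus compound ``i`` in
    sample ``j`` (0 = not detected); ``quality`` holds the matching per-cell
    quality scores.  ``provenance[i]`` lists the (sample index, feature row)
    pairs absorbed into consensus ``i``.
    """

    consensus: pd.DataFrame          # columns mz_ref, rt_ref
    abundance: np.ndarray            # (n_consensus, n_samples)
    quality: np.ndarray              # same shape
    sample_ids: list[str]
    classes: np.ndarray              # per-sample species label
    roles: np.ndarray                # per-sample role (oil/blank/mixture/panel)
    provenance: list[list[tuple[int, int]]] = field(default_factory=list)

    @property
    def n_consensus(self) -> int:
        return len(self.consensus)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def detected(self) -> np.ndarray:
        return self.abundance > 0

    def column_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def class_columns(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.classes == label)

    def subset_rows(self, rows) -> "FeatureMatrix":
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return FeatureMatrix(
            consensus=self.consensus.iloc[rows].reset_index(drop=True),
            abundance=self.abundance[rows],
            quality=self.quality[rows],
            sample_ids=list(self.sample_ids),
            classes=self.classes.copy(),
            roles=self.roles.copy(),
            provenance=[self.provenance[i] for i in rows] if self.provenance else [],
        )


def filter_compound_abundance(sample: Sample, min_compound_abundance: float) -> Sample:
    """Drop features whose integrated compound abundance is below the
    molecular-feature-extraction minimum (vendor default 50,000 counts)."""
    if min_compound_abundance <= 0:
        return sample
    out = sample.copy()
    out.features = out.features[
        out.features["abundance"] >= min_compound_abundance
    ].reset_index(drop=True)
    return out


def align(samples: list[Sample], w: ToleranceWindows | None = None) -> FeatureMatrix:
    """Align features across samples into a :class:`FeatureMatrix`.

    Every input feature is assigned to exactly one consensus compound; the
    consensus (mz_ref, rt_ref) is the intensity-weighted mean of its members.
    """
    if not samples:
        raise ValueError("align requires at least one sample")
    check_unique_ids(samples)
    w = w or ToleranceWindows()

    frames = []
    for j, s in enumerate(samples):
        f = s.features
        frames.append(
            np.column_stack(
                [
                    f["mz"].to_numpy(),
                    f["rt_min"].to_numpy(),
                    f["height"].to_numpy(),
                    f["quality"].to_numpy(),
                    np.full(len(f), j, dtype=float),
                    np.arange(len(f), dtype=float),
                ]
            )
        )
    all_feats = (
        np.vstack(frames) if frames else np.empty((0, 6))
    )
    n = len(all_feats)
    n_samples = len(samples)
    if n == 0:
        return FeatureMatrix(
            consensus=pd.DataFrame(columns=["mz_ref", "rt_ref"]),
            abundance=np.zeros((0, n_samples)),
            quality=np.zeros((0, n_samples)),
            sample_ids=[s.id for s in samples],
            classes=np.array([s.species for s in samples]),
            roles=np.array([s.role for s in samples]),
            provenance=[],
        )

    mz, rt, height = all_feats[:, 0], all_feats[:, 1], all_feats[:, 2]
    samp = all_feats[:, 4].astype(int)
    row = all_feats[:, 5].astype(int)

    # canonical pre-sort: descending height, then mz, rt, sample, row
    order = np.lexsort((row, samp, rt, mz, -height))
    # mz-sorted view for windowed candidate lookup
    mz_order = np.argsort(mz, kind="stable")
    mz_sorted = mz[mz_order]

    def absorb(center_mz, center_rt, assigned, cid):
        """Assign unassigned features whose windows overlap the centre's
        window (|d| <= hw_centre + hw_feature on both axes) to cluster
        ``cid`` (at most one per sample; best |dmz|, |drt|, order)."""
        mz_hw = center_mz * w.mz_ppm * 1e-6 + w.mz_abs
        rt_hw = center_rt * w.rt_rel + w.rt_abs
        lo = np.searchsorted(mz_sorted, center_mz - 2.5 * mz_hw, side="left")
        hi = np.searchsorted(mz_sorted, center_mz + 2.5 * mz_hw, side="right")
        cand = mz_order[lo:hi]
        cand = cand[
            (assigned[cand] < 0)
            & (np.abs(mz[cand] - center_mz) <= mz_hw + w.mz_halfwidth(mz[cand]))
            & (np.abs(rt[cand] - center_rt) <= rt_hw + w.rt_halfwidth(rt[cand]))
        ]
        if len(cand) > 1:
            key = np.lexsort(
                (cand, np.abs(rt[cand] - center_rt), np.abs(mz[cand] - center_mz))
            )
            cand = cand[key]
            seen = set()
            keep = []
            for c in cand:
                if samp[c] not in seen:
                    seen.add(samp[c])
                    keep.append(c)
            cand = np.array(keep)
        assigned[cand] = cid
        return cand

    def weighted_ref(members):
        h = height[members]
        wts = h / h.sum() if h.sum() > 0 else np.full(len(members), 1.0 / len(members))
        return float(mz[members] @ wts), float(rt[members] @ wts)

    # pass 1: seed-centred greedy clustering
    assigned = np.full(n, -1, dtype=int)
    clusters: list[np.ndarray] = []
    for idx in order:
        if assigned[idx] >= 0:
            continue
        clusters.append(absorb(mz[idx], rt[idx], assigned, len(clusters)))

    # pass 2: recentre on the consensus references and re-assign
    refs = [weighted_ref(c) for c in clusters]
    totals = np.array([height[c].sum() for c in clusters])
    ref_order = np.lexsort(
        ([r[1] for r in refs], [r[0] for r in refs], -totals)
    )
    assigned = np.full(n, -1, dtype=int)
    clusters2: list[np.ndarray] = []
    for old_cid in ref_order:
        members = absorb(refs[old_cid][0], refs[old_cid][1], assigned, len(clusters2))
        if len(members):
            clusters2.append(members)
    for idx in order:  # features orphaned by the moved centres seed afresh
        if assigned[idx] >= 0:
            continue
        clusters2.append(absorb(mz[idx], rt[idx], assigned, len(clusters2)))
    clusters = clusters2

    n_cons = len(clusters)
    abundance = np.zeros((n_cons, n_samples))
    quality = np.zeros((n_cons, n_samples))
    mz_ref = np.empty(n_cons)
    rt_ref = np.empty(n_cons)
    provenance: list[list[tuple[int, int]]] = []
    for cid, members in enumerate(clusters):
        h = height[members]
        wsum = h.sum()
        if wsum <= 0:
            wts = np.full(len(members), 1.0 / len(members))
        else:
            wts = h / wsum
        mz_ref[cid] = float(mz[members] @ wts)
        rt_ref[cid] = float(rt[members] @ wts)
        abundance[cid, samp[members]] = h
        quality[cid, samp[members]] = all_feats[members, 3]
        provenance.append([(int(samp[m]), int(row[m])) for m in members])

    # present consensus compounds in (mz, rt) order
    pres = np.lexsort((rt_ref, mz_ref))
    return FeatureMatrix(
        consensus=pd.DataFrame({"mz_ref": mz_ref[pres], "rt_ref": rt_ref[pres]}),
        abundance=abundance[pres],
        quality=quality[pres],
        sample_ids=[s.id for s in samples],
        classes=np.array([s.species for s in samples]),
        roles=np.array([s.role for s in samples]),
        provenance=[provenance[i] for i in pres],
    )


def filter_flags(
    matrix: FeatureMatrix, min_height: float = 600.0, min_quality: float = 80.0
) -> FeatureMatrix:
    """Zero cells failing the height/quality flags (inclusive thresholds) and
    drop consensus compounds left with all-zero abundance."""
    out = matrix.subset_rows(np.arange(matrix.n_consensus))
    bad = (out.abundance < min_height) | (out.quality < min_quality)
    out.abundance = np.where(bad, 0.0, out.abundance)
    out.quality = np.where(bad, 0.0, out.quality)
    keep = out.abundance.sum(axis=1) > 0
    return out.subset_rows(keep)


def filter_frequency(
    matrix: FeatureMatrix, class_label: str, min_fraction: float = 1.0
) -> np.ndarray:
    """Boolean mask of consensus compounds detected in at least
    ``min_fraction`` of the samples of ``class_label``.

    The default 1.0 mirrors keeping only compounds found in every sample of
    an oil type; ``min_fraction=0`` is the identity on detected features.
    """
    cols = matrix.class_columns(class_label)
    if len(cols) == 0:
        raise ValueError(f"class {class_label!r} absent from matrix")
    frac = matrix.detected()[:, cols].mean(axis=1)
    return frac >= min_fraction


def subtract_blanks(
    matrix: FeatureMatrix,
    blank_ids: list[str] | None = None,
    w: ToleranceWindows | None = None,
) -> FeatureMatrix:
    """Remove consensus compounds traceable to the solvent blanks.

    A compound is removed if it is detected in any blank run, or if its
    reference (m/z, RT) lies within the alignment windows of such a
    blank-detected compound (covering the case where the blank's ion aligned
    into a neighbouring consensus).
    """
    w = w or ToleranceWindows()
    if blank_ids is None:
        cols = np.flatnonzero(matrix.roles == "blank")
    else:
        cols = np.array([matrix.column_index(b) for b in blank_ids], dtype=int)
    if len(cols) == 0:
        return matrix.subset_rows(np.arange(matrix.n_consensus))
    in_blank = matrix.detected()[:, cols].any(axis=1)
    mz_ref = matrix.consensus["mz_ref"].to_numpy()
    rt_ref = matrix.consensus["rt_ref"].to_numpy()
    drop = in_blank.copy()
    bmz, brt = mz_ref[in_blank], rt_ref[in_blank]
    for m, t in zip(bmz, brt):
        near = (np.abs(mz_ref - m) <= w.mz_halfwidth(m)) & (
            np.abs(rt_ref - t) <= w.rt_halfwidth(t)
        )
        drop |= near
    return matrix.subset_rows(~drop)
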