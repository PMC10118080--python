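"""Marker discovery, targeted screening and mixture detection limits.

Discovery follows the authentication workflow: candidate ions for a target
oil must (i) be detected in every sample of that oil, (ii) be absent from the
full negative panel — the other target species plus the marker-free panel
species, 64 runs in the default design — within the alignment windows, and
(iii) rank by their OPLS-DA importance (VIP).  Exclusivity is the binding
criterion; the VIP threshold is exposed for stricter selections.

Screening inverts this: given a marker library, an unknown run is searched
for each marker's precursor within the m/z window and within
``rt_tol x multiplier`` of the library retention time, optionally requiring
MS/MS fragment confirmation.  A declared species is "authentic-consistent"
when all of its markers are found.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alignment_filtering import FeatureMatrix
from .chemometrics import OplsDaModel, fit_oplsda, variable_contributions
from .types import MarkerRecord, MixtureSpec, Sample, ToleranceWindows
from .synthetic_data import (
    SimulationDesign,
    default_species,
    simulate_dataset,
    simulate_mixture,
)

#: Who gets diluted into whom when preparing mixtures: the three other oils
#: into sunflower, and sunflower itself into rapeseed.
MIXTURE_SCHEME = {
    "flax": "sunflower",
    "sesame": "sunflower",
    "rapeseed": "sunflower",
    "sunflower": "rapeseed",
}


@dataclass(frozen=True)
class CandidateMarker:
    mz_ref: float
    rt_ref: float
    target_class: str
    vip: float
    contribution: float
    class_frequency: float
    panel_hits: int


@dataclass(frozen=True)
class ScreeningHit:
    marker: MarkerRecord
    sample_id: str
    mz: float
    rt: float
    height: float
    mz_error_ppm: float
    rt_error_min: float
    fragments_matched: int


def fit_class_model(
    matrix: FeatureMatrix,
    n_predictive: int = 3,
    n_orthogonal: int = 2,
    cv_folds: int = 7,
) -> tuple[OplsDaModel, np.ndarray]:
    """OPLS-DA of the oil-role samples of a feature matrix (classes = species).

    Returns the model and the oil-sample column indices it was fitted on.
    """
    cols = np.flatnonzero(matrix.roles == "oil")
    if len(cols) == 0:
        raise ValueError("matrix holds no oil-role samples")
    X = matrix.abundance[:, cols].T
    classes = matrix.classes[cols]
    model = fit_oplsda(X, classes, n_predictive, n_orthogonal, cv_folds=cv_folds)
    return model, cols


def discover_markers(
    matrix: FeatureMatrix,
    target_class: str,
    panel_classes: Sequence[str],
    windows: ToleranceWindows | None = None,
    vip_threshold: float = 0.0,
    model: OplsDaModel | None = None,
    n_predictive: int = 3,
    n_orthogonal: int = 2,
) -> list[CandidateMarker]:
    """Species-specific candidate markers from a filtered feature matrix.

    ``matrix`` should already be flag-filtered and blank-subtracted.  A
    candidate must be present in 100 % of the target-class oil samples,
    absent from every negative-panel sample, and carry VIP >= threshold;
    candidates are returned sorted by descending VIP.
    """
    windows = windows or ToleranceWindows()
    target_cols = np.flatnonzero(
        (matrix.classes == target_class) & (matrix.roles == "oil")
    )
    if len(target_cols) == 0:
        raise ValueError(f"target class {target_class!r} absent from matrix")
    panel_cols = np.flatnonzero(np.isin(matrix.classes, list(panel_classes)))
    det = matrix.detected()
    freq = det[:, target_cols].mean(axis=1)
    panel_hits = det[:, panel_cols].sum(axis=1)

    if model is None:
        model, _ = fit_class_model(
            matrix, n_predictive=n_predictive, n_orthogonal=n_orthogonal, cv_folds=None
        )
    oil_cols = np.flatnonzero(matrix.roles == "oil")
    vip = np.zeros(matrix.n_consensus)
    contrib = np.zeros(matrix.n_consensus)
    kept = model.scaler.kept if model.scaler is not None else np.arange(matrix.n_consensus)
    vip[kept] = model.vip
    contrib[kept] = variable_contributions(model, target_class, matrix.classes[oil_cols])

    sel = np.flatnonzero((freq >= 1.0) & (panel_hits == 0) & (vip >= vip_threshold))
    sel = sel[np.argsort(-vip[sel], kind="stable")]
    return [
        CandidateMarker(
            mz_ref=float(matrix.consensus["mz_ref"].iloc[i]),
            rt_ref=float(matrix.consensus["rt_ref"].iloc[i]),
            target_class=target_class,
            vip=float(vip[i]),
            contribution=float(contrib[i]),
            class_frequency=float(freq[i]),
            panel_hits=int(panel_hits[i]),
        )
        for i in sel
    ]


def match_candidates_to_library(
    candidates: Sequence[CandidateMarker],
    library: Sequence[MarkerRecord],
    windows: ToleranceWindows | None = None,
    rt_tol_multiplier: float = 3.0,
) -> dict[int, Optional[CandidateMarker]]:
    """Map library marker numbers to the discovered candidate matching them
    (None when a marker was not recovered)."""
    windows = windows or ToleranceWindows()
    out: dict[int, Optional[CandidateMarker]] = {}
    for m in library:
        hw = windows.mz_halfwidth(m.precursor_mz)
        best = None
        for c in candidates:
            if (
                abs(c.mz_ref - m.precursor_mz) <= hw
                and abs(c.rt_ref - m.rt_mean) <= m.rt_tol * rt_tol_multiplier
            ):
                if best is None or abs(c.mz_ref - m.precursor_mz) < abs(
                    best.mz_ref - m.precursor_mz
                ):
                    best = c
        out[m.number] = best
    return out


def screen_sample(
    sample: Sample,
    library: Sequence[MarkerRecord],
    windows: ToleranceWindows | None = None,
    rt_tol_multiplier: float = 3.0,
    ms2_spectra: dict[int, Sequence[float]] | None = None,
    min_fragments: int = 0,
) -> tuple[list[ScreeningHit], pd.DataFrame]:
    """Targeted screen of one run against a marker library.

    Returns the per-marker hits and a per-oil summary with the hit count and
    an ``complete`` flag (all markers of that oil present).  When MS/MS
    spectra are supplied (marker number -> fragment m/z list), hits must
    confirm at least ``min_fragments`` library fragments within the m/z
    window.
    """
    if not library:
        raise ValueError("empty marker library")
    windows = windows or ToleranceWindows()
    mz = sample.features["mz"].to_numpy()
    rt = sample.features["rt_min"].to_numpy()
    height = sample.features["height"].to_numpy()
    hits: list[ScreeningHit] = []
    for m in library:
        hw = windows.mz_halfwidth(m.precursor_mz)
        rt_hw = m.rt_tol * rt_tol_multiplier
        cand = np.flatnonzero(
            (np.abs(mz - m.precursor_mz) <= hw) & (np.abs(rt - m.rt_mean) <= rt_hw)
        )
        if len(cand) == 0:
            continue
        best = cand[
            np.lexsort(
                (np.abs(rt[cand] - m.rt_mean), np.abs(mz[cand] - m.precursor_mz))
            )[0]
        ]
        n_frag = 0
        if ms2_spectra is not None and m.number in ms2_spectra:
            spec_mz = np.asarray(list(ms2_spectra[m.number]), dtype=float)
            for f in m.fragments:
                if np.any(np.abs(spec_mz - f) <= windows.mz_halfwidth(f)):
                    n_frag += 1
            if n_frag < min_fragments:
                continue
        hits.append(
            ScreeningHit(
                marker=m,
                sample_id=sample.id,
                mz=float(mz[best]),
                rt=float(rt[best]),
                height=float(height[best]),
                mz_error_ppm=float((mz[best] - m.precursor_mz) / m.precursor_mz * 1e6),
                rt_error_min=float(rt[best] - m.rt_mean),
                fragments_matched=n_frag,
            )
        )
    oils = sorted({m.oil for m in library})
    hit_numbers = {h.marker.number for h in hits}
    summary = pd.DataFrame(
        [
            {
                "oil": oil,
                "n_markers": sum(m.oil == oil for m in library),
                "n_hits": sum(m.oil == oil and m.number in hit_numbers for m in library),
            }
            for oil in oils
        ]
    )
    summary["complete"] = summary["n_hits"] == summary["n_markers"]
    return hits, summary


def mixture_detection_table(
    library: Sequence[MarkerRecord] | None = None,
    design: SimulationDesign | None = None,
    fractions: Sequence[float] = (0.01, 0.05),
    windows: ToleranceWindows | None = None,
    rt_tol_multiplier: float = 3.0,
) -> pd.DataFrame:
    """Per-marker detectability in simulated two-component mixtures.

    For every library marker and every fraction, one mixture is simulated
    under ``design`` (the minor oil diluted into its scheme partner) and
    screened; ``detected`` records whether the marker survived the dilution
    and the detection floor.  With the default noise-free design and the
    calibrated base intensities this reproduces the library's +/- flags.
    """
    from .io_formats import read_marker_library

    library = list(library) if library is not None else read_marker_library()
    design = design or SimulationDesign().noise_free()
    targets, _ = default_species(library, background_share=design.background_share)
    samples, _ = simulate_dataset(design, species=targets, panel=[])
    rep = {s.species: s for s in samples if s.producer == "a" and s.batch == "1"}
    by_oil: dict[str, list[MarkerRecord]] = {}
    for m in library:
        by_oil.setdefault(m.oil, []).append(m)
    rows = []
    for oil, markers in by_oil.items():
        major = MIXTURE_SCHEME.get(oil)
        if major is None or major not in rep or oil not in rep:
            raise ValueError(f"no mixture partner available for {oil!r}")
        for f in fractions:
            mix = simulate_mixture(
                rep[oil], rep[major], MixtureSpec(oil, major, f), design, windows
            )
            hits, _ = screen_sample(
                mix, markers, windows=windows, rt_tol_multiplier=rt_tol_multiplier
            )
            found = {h.marker.number for h in hits}
            for m in markers:
                rows.append(
                    {
                        "oil": oil,
                        "number": m.number,
                        "fraction": f,
                        "detected": m.number in found,
                    }
                )
    return pd.DataFrame(rows).sort_values(["number", "fraction"]).reset_index(drop=True)


def abundance_variability(heights) -> float | None:
    """Percent spread of a marker's signal across samples where detected:
    100 x (max - min) / max.  Undefined (None) when never detected; a single
    detection gives 0 by convention."""
    h = np.asarray([x for x in np.atleast_1d(heights) if x and x > 0], dtype=float)
    if h.size == 0:
        return None
    if h.size == 1:
        return 0.0
    return float(100.0 * (h.max() - h.min()) / h.max())
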