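"""Synthetic LC-MS study generator.

Emulates the structure of a cold-pressed seed-oil authentication study:
4 target oil species (sunflower, rapeseed, sesame, flax) x 4 producers
(a-d) x 2 batches, a negative panel of 5 further oil species bought from the
same producers (so each target oil faces 8 other species / 64 samples), blank
solvent runs, and two-component v/v mixtures.

Intensity model
---------------
Each species expresses its library markers plus a share of a common
background metabolome plus a fixed solvent-contaminant set.  A feature's
height in a sample is

    base x exp(producer effect) x exp(batch effect)

with lognormal producer/batch effects drawn per feature (defaults 0.5 / 0.2
on the log scale, chosen so the max-min signal spread across the 8 samples of
a species falls in the ~50-90 % range typical of commercial oils).  Observed
m/z gets ppm-scaled Gaussian noise, RT gets absolute Gaussian jitter, and
features below the detection floor (600 counts) are censored.

Marker base intensities are calibrated against the library's 1 %-mixture
detectability flags: with a 600-count floor, a marker survives 1 % dilution
iff its base height is >= 60,000 counts, so flagged-detectable markers get
bases >= 60,000 and the faint ones 40,000.

Everything is driven by `numpy.random.default_rng` seeded from the design
seed, so a given design reproduces bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import MarkerRecord, MixtureSpec, Sample, ToleranceWindows
from .io_formats import read_marker_library

TARGET_SPECIES = ["sunflower", "rapeseed", "sesame", "flax"]
PANEL_SPECIES = ["pumpkin", "evening_primrose", "black_cumin", "hemp", "thistle"]

#: Base peak height (counts) for markers detectable in a 1 % mixture.
BASE_DETECTABLE = 150_000.0
#: Base height for the most intense markers of each oil.
BASE_HIGH = 300_000.0
#: Base height for markers not detectable at 1 % (must be < 60,000).
BASE_FAINT = 40_000.0
#: Library numbers of the markers reported as the most intense per oil.
HIGH_INTENSITY_NUMBERS = {4, 6, 8, 9, 17, 20, 23, 25}

#: Abundance (integrated counts) emitted per unit of apex height.
ABUNDANCE_PER_HEIGHT = 100.0


@dataclass(frozen=True)
class OilSpeciesSpec:
    """One simulated species: its markers (empty for panel species), the
    base intensity per marker number, and the fraction of the common
    background metabolome it expresses."""

    name: str
    markers: tuple[MarkerRecord, ...] = ()
    base_intensity: dict = field(default_factory=dict)
    background_share: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_share <= 1.0:
            raise ValueError("background_share must lie in [0, 1]")
        w = ToleranceWindows()
        mzs = sorted(m.precursor_mz for m in self.markers)
        for a, b in zip(mzs, mzs[1:]):
            if b - a <= w.mz_halfwidth(a):
                raise ValueError(
                    f"{self.name}: marker precursors {a} and {b} are not "
                    "resolved at 5 ppm + 2 mDa"
                )


@dataclass(frozen=True)
class SimulationDesign:
    """Study layout and noise levels of a simulated dataset."""

    n_producers: int = 4
    n_batches: int = 2
    producer_log_sd: float = 0.5
    producer_shared_log_sd: float = 0.3
    batch_log_sd: float = 0.2
    sample_log_sd: float = 0.15
    mass_error_ppm_sd: float = 1.5
    rt_drift_abs_min: float = 0.05
    detection_floor_counts: float = 600.0
    n_background: int = 500
    n_solvent: int = 40
    background_share: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(
            self.producer_log_sd,
            self.producer_shared_log_sd,
            self.batch_log_sd,
            self.sample_log_sd,
            self.mass_error_ppm_sd,
            self.rt_drift_abs_min,
        ) < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.detection_floor_counts <= 0:
            raise ValueError("detection floor must be positive")
        if self.n_producers < 1 or self.n_batches < 1:
            raise ValueError("need at least one producer and one batch")

    def noise_free(self) -> "SimulationDesign":
        from dataclasses import replace

        return replace(
            self,
            producer_log_sd=0.0,
            producer_shared_log_sd=0.0,
            batch_log_sd=0.0,
            sample_log_sd=0.0,
            mass_error_ppm_sd=0.0,
            rt_drift_abs_min=0.0,
        )


def marker_base_intensity(m: MarkerRecord) -> float:
    if not m.detect_1pct:
        return BASE_FAINT
    return BASE_HIGH if m.number in HIGH_INTENSITY_NUMBERS else BASE_DETECTABLE


def default_species(
    library: Sequence[MarkerRecord] | None = None,
    background_share: float = 0.8,
) -> tuple[list[OilSpeciesSpec], list[OilSpeciesSpec]]:
    """Target species seeded with the packaged marker library, plus the
    marker-free negative-panel species."""
    library = list(library) if library is not None else read_marker_library()
    targets = []
    for name in TARGET_SPECIES:
        markers = tuple(m for m in library if m.oil == name)
        targets.append(
            OilSpeciesSpec(
                name=name,
                markers=markers,
                base_intensity={m.number: marker_base_intensity(m) for m in markers},
                background_share=background_share,
            )
        )
    panel = [
        OilSpeciesSpec(name=n, background_share=background_share)
        for n in PANEL_SPECIES
    ]
    return targets, panel


# ------------------------------------------------------------ shared tables

def background_features(design: SimulationDesign) -> pd.DataFrame:
    """The common background metabolome shared (partially) by all species."""
    rng = np.random.default_rng([design.seed, 101])
    n = design.n_background
    return pd.DataFrame(
        {
            "mz": np.sort(rng.uniform(100.0, 900.0, n)),
            "rt_min": rng.uniform(0.5, 29.0, n),
            "base": np.clip(rng.lognormal(np.log(30_000.0), 1.0, n), 2_000.0, None),
        }
    )


def solvent_features(design: SimulationDesign) -> pd.DataFrame:
    """Solvent/system contaminant ions present in every run including blanks.

    Their mass defect is confined to [0.70, 0.95], far from the small-molecule
    defects of the marker library, so blanks and markers never collide.
    """
    rng = np.random.default_rng([design.seed, 102])
    n = design.n_solvent
    return pd.DataFrame(
        {
            "mz": np.floor(rng.uniform(80.0, 600.0, n)) + rng.uniform(0.70, 0.95, n),
            "rt_min": rng.uniform(0.3, 29.5, n),
            "base": rng.lognormal(np.log(20_000.0), 0.3, n),
        }
    )


def _species_index(name: str) -> int:
    order = TARGET_SPECIES + PANEL_SPECIES
    if name in order:
        return order.index(name)
    return 100 + (abs(hash(name)) % 1_000_000)


def _species_feature_table(spec: OilSpeciesSpec, design: SimulationDesign) -> pd.DataFrame:
    """Per-species list of (mz, rt, base) it can express: markers + its
    background subset + the solvent set."""
    bg = background_features(design)
    solv = solvent_features(design)
    sidx = _species_index(spec.name)
    rng = np.random.default_rng([design.seed, 201, sidx])
    n_bg = len(bg)
    n_keep = int(round(spec.background_share * n_bg))
    keep = np.sort(rng.choice(n_bg, size=n_keep, replace=False))
    rows = []
    for m in spec.markers:
        rows.append(
            {
                "mz": m.precursor_mz,
                "rt_min": m.rt_mean,
                "base": spec.base_intensity.get(m.number, BASE_DETECTABLE),
                "kind": "marker",
                "ref": m.number,
            }
        )
    for i in keep:
        rows.append(
            {
                "mz": bg.at[i, "mz"],
                "rt_min": bg.at[i, "rt_min"],
                "base": bg.at[i, "base"],
                "kind": "background",
                "ref": int(i),
            }
        )
    for i in range(len(solv)):
        rows.append(
            {
                "mz": solv.at[i, "mz"],
                "rt_min": solv.at[i, "rt_min"],
                "base": solv.at[i, "base"],
                "kind": "solvent",
                "ref": int(i),
            }
        )
    return pd.DataFrame(rows)


def _emit_sample(
    table: pd.DataFrame,
    heights: np.ndarray,
    design: SimulationDesign,
    rng: np.random.Generator,
    **meta,
) -> Sample:
    """Apply m/z and RT noise, censor at the detection floor, build a Sample."""
    n = len(table)
    mz = table["mz"].to_numpy() * (
        1.0 + rng.normal(0.0, design.mass_error_ppm_sd, n) * 1e-6
    )
    rt = np.clip(
        table["rt_min"].to_numpy() + rng.normal(0.0, design.rt_drift_abs_min, n),
        0.01,
        30.0,
    )
    quality = rng.uniform(81.0, 100.0, n)
    keep = heights >= design.detection_floor_counts
    feats = pd.DataFrame(
        {
            "mz": mz[keep],
            "rt_min": rt[keep],
            "height": heights[keep],
            "quality": quality[keep],
            "abundance": heights[keep] * ABUNDANCE_PER_HEIGHT,
        }
    ).sort_values(["mz", "rt_min"], kind="stable").reset_index(drop=True)
    return Sample(features=feats, **meta)


def simulate_dataset(
    design: SimulationDesign,
    species: Sequence[OilSpeciesSpec] | None = None,
    panel: Sequence[OilSpeciesSpec] | None = None,
) -> tuple[list[Sample], dict]:
    """Simulate all producer x batch samples for the given species.

    Returns the samples (role ``oil`` for species with markers, ``panel``
    otherwise) and the ground-truth manifest of planted identities, which is
    written alongside the data but never read by the pipeline.
    """
    if species is None:
        species, default_panel = default_species(background_share=design.background_share)
        panel = default_panel if panel is None else panel
    all_specs = list(species) + list(panel or [])
    if not all_specs:
        raise ValueError("simulate_dataset needs at least one species")
    producers = [chr(ord("a") + i) for i in range(design.n_producers)]
    if len(set(producers)) != design.n_producers:
        raise ValueError("producer labels must be unique")
    samples: list[Sample] = []
    truth: dict = {
        "design": asdict(design),
        "species": {},
        "solvent_mz": solvent_features(design)["mz"].round(6).tolist(),
    }
    for spec in all_specs:
        sidx = _species_index(spec.name)
        table = _species_feature_table(spec, design)
        n_feat = len(table)
        rng_prod = np.random.default_rng([design.seed, 301, sidx])
        rng_batch = np.random.default_rng([design.seed, 302, sidx])
        # producer effect = a factor shared by all of a producer's features
        # (pressing yield / seed-lot concentration) + a per-feature part
        prod_shared = rng_prod.normal(
            0.0, design.producer_shared_log_sd, (design.n_producers, 1)
        )
        prod_eff = prod_shared + rng_prod.normal(
            0.0, design.producer_log_sd, (design.n_producers, n_feat)
        )
        batch_eff = rng_batch.normal(
            0.0, design.batch_log_sd, (design.n_producers, design.n_batches, n_feat)
        )
        role = "oil" if spec.markers else "panel"
        for pi, prod in enumerate(producers):
            for bi in range(design.n_batches):
                rng_obs = np.random.default_rng([design.seed, 303, sidx, pi, bi])
                # one global factor per run: injection/extraction variability
                run_scale = np.exp(rng_obs.normal(0.0, design.sample_log_sd))
                heights = (
                    table["base"].to_numpy()
                    * run_scale
                    * np.exp(prod_eff[pi] + batch_eff[pi, bi])
                )
                samples.append(
                    _emit_sample(
                        table,
                        heights,
                        design,
                        rng_obs,
                        id=f"{spec.name}_{prod}{bi + 1}",
                        species=spec.name,
                        producer=prod,
                        batch=str(bi + 1),
                        role=role,
                    )
                )
        truth["species"][spec.name] = {
            "role": role,
            "markers": [
                {
                    "number": int(m.number),
                    "mz": m.precursor_mz,
                    "rt": m.rt_mean,
                    "base": spec.base_intensity.get(m.number, BASE_DETECTABLE),
                }
                for m in spec.markers
            ],
            "background_ref": table.loc[table["kind"] == "background", "ref"].tolist(),
        }
    return samples, truth


def simulate_blank(design: SimulationDesign, index: int = 1) -> Sample:
    """One solvent-blank run: only the contaminant set, with batch-level
    intensity noise and the usual m/z / RT jitter."""
    solv = solvent_features(design)
    rng = np.random.default_rng([design.seed, 401, index])
    heights = solv["base"].to_numpy() * np.exp(
        rng.normal(0.0, design.batch_log_sd, len(solv))
    )
    table = solv.rename(columns={"base": "height"})[["mz", "rt_min"]].assign(
        base=solv["base"]
    )
    return _emit_sample(
        table.assign(kind="solvent"),
        heights,
        design,
        rng,
        id=f"blank_{index}",
        species="blank",
        role="blank",
    )


def simulate_study(
    design: SimulationDesign, n_blanks: int = 4
) -> tuple[list[Sample], dict]:
    """Full default study: 4 target oils + 5 panel species + blanks."""
    samples, truth = simulate_dataset(design)
    for i in range(n_blanks):
        samples.append(simulate_blank(design, index=i + 1))
    return samples, truth


def simulate_mixture(
    sample_minor: Sample,
    sample_major: Sample,
    spec: MixtureSpec,
    design: SimulationDesign,
    windows: ToleranceWindows | None = None,
) -> Sample:
    """Two-component v/v mixture of two runs simulated under one design.

    Minor-oil features are scaled by the volume fraction f, major by 1 - f;
    co-eluting features (within the alignment windows) are summed, then the
    detection floor is applied.
    """
    w = windows or ToleranceWindows()
    f = spec.fraction
    parts = []
    for s, scale in ((sample_minor, f), (sample_major, 1.0 - f)):
        df = s.features.copy()
        df["height"] *= scale
        df["abundance"] *= scale
        parts.append(df)
    merged = pd.concat(parts, ignore_index=True)
    mz = merged["mz"].to_numpy()
    rt = merged["rt_min"].to_numpy()
    h = merged["height"].to_numpy()
    order = np.argsort(-h, kind="stable")
    assigned = np.full(len(merged), -1, dtype=int)
    groups: list[list[int]] = []
    mz_order = np.argsort(mz, kind="stable")
    mz_sorted = mz[mz_order]
    for idx in order:
        if assigned[idx] >= 0:
            continue
        gid = len(groups)
        mz_hw = w.mz_halfwidth(mz[idx])
        rt_hw = w.rt_halfwidth(rt[idx])
        lo = np.searchsorted(mz_sorted, mz[idx] - mz_hw, "left")
        hi = np.searchsorted(mz_sorted, mz[idx] + mz_hw, "right")
        cand = mz_order[lo:hi]
        cand = cand[(assigned[cand] < 0) & (np.abs(rt[cand] - rt[idx]) <= rt_hw)]
        assigned[cand] = gid
        groups.append(list(cand))
    rows = []
    for g in groups:
        g = np.asarray(g)
        hh = h[g]
        wts = hh / hh.sum() if hh.sum() > 0 else np.full(len(g), 1.0 / len(g))
        rows.append(
            {
                "mz": float(mz[g] @ wts),
                "rt_min": float(rt[g] @ wts),
                "height": float(hh.sum()),
                "quality": float(merged["quality"].to_numpy()[g].max()),
                "abundance": float(merged["abundance"].to_numpy()[g].sum()),
            }
        )
    feats = pd.DataFrame(rows)
    feats = feats[feats["height"] >= design.detection_floor_counts]
    feats = feats.sort_values(["mz", "rt_min"], kind="stable").reset_index(drop=True)
    return Sample(
        id=f"mix_{spec.minor_species}_{int(round(f * 100))}pct_in_{spec.major_species}",
        species="mixture",
        role="mixture",
        features=feats,
        mixture=spec,
    )


# ----------------------------------------------------------- assay plates

@dataclass
class AssayPlate:
    """Simulated microplate readings for one assay on one sample.

    For ABTS the plate holds control absorbance Ac and sample absorbances
    over a dilution series of oil concentrations (kg oil / l assay), plus the
    matching Trolox standard series (mg/l).  For TPC/TCC it holds replicate
    sample absorbances at one oil concentration and the standard-curve
    points (ug/ml vs absorbance).
    """

    kind: str                                   # ABTS | TPC | TCC
    n_replicates: int
    control_absorbance: Optional[float] = None
    sample_concentrations: Optional[np.ndarray] = None
    sample_absorbances: Optional[np.ndarray] = None      # (reps, n_conc) or (reps,)
    standard_concentrations: Optional[np.ndarray] = None
    standard_absorbances: Optional[np.ndarray] = None    # (reps, n_std) or (n_std,)
    oil_concentration: Optional[float] = None            # kg oil / l assay
    dilution: float = 1.0
    blank_absorbance: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in {"ABTS", "TPC", "TCC"}:
            raise ValueError(f"unknown assay kind {self.kind!r}")


def _hill(conc, ec50):
    conc = np.asarray(conc, dtype=float)
    return 100.0 * conc / (conc + ec50)


def simulate_assay_plate(
    kind: str,
    true_value: float,
    curve_params: tuple[float, float] | None = None,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    oil_concentration: float | None = None,
    ec50_trolox: float = 4.0,
    control_absorbance: float = 0.70,
    blank_absorbance: float = 0.0,
) -> AssayPlate:
    """Generate plate readings whose analysis recovers ``true_value``.

    ``true_value`` units: ABTS -> mg Trolox / kg oil (TEAC); TPC -> mg gallic
    acid / kg oil; TCC -> mg beta-carotene / kg oil.  ``noise_sd`` is the
    relative (multiplicative) absorbance noise.  ``curve_params`` is
    (slope per ug/ml, intercept) for the linear calibrations.
    """
    rng = np.random.default_rng(seed)

    def jitter(a):
        a = np.asarray(a, dtype=float)
        return a * (1.0 + rng.normal(0.0, noise_sd, a.shape)) if noise_sd > 0 else a

    if kind == "ABTS":
        if true_value <= 0:
            raise ValueError("TEAC must be positive")
        if oil_concentration is None:
            oil_concentration = 2e-3
        ec50_oil = ec50_trolox / true_value  # kg oil / l assay
        concs = ec50_oil * np.geomspace(0.15, 8.0, 9)
        red = _hill(concs, ec50_oil)
        As = control_absorbance * (1.0 - red / 100.0)
        sample_abs = jitter(np.tile(As, (n_replicates, 1)))
        std_concs = ec50_trolox * np.geomspace(0.15, 8.0, 9)
        std_red = _hill(std_concs, ec50_trolox)
        std_abs = jitter(
            np.tile(control_absorbance * (1.0 - std_red / 100.0), (n_replicates, 1))
        )
        return AssayPlate(
            kind=kind,
            n_replicates=n_replicates,
            control_absorbance=control_absorbance,
            sample_concentrations=concs,
            sample_absorbances=sample_abs,
            standard_concentrations=std_concs,
            standard_absorbances=std_abs,
        )

    if curve_params is None:
        curve_params = (0.005, 0.02) if kind == "TPC" else (0.002, 0.01)
    if oil_concentration is None:
        # chosen so typical oil values land mid-curve: TPC readings use the
        # concentrated methanolic extract, TCC a 10-fold dilution
        oil_concentration = 1.0 if kind == "TPC" else 0.1
    slope, intercept = curve_params
    std_concs = (
        np.array([25.0, 50.0, 100.0, 150.0, 200.0])
        if kind == "TPC"
        else np.array([5.0, 25.0, 100.0, 250.0, 500.0])
    )
    std_abs = blank_absorbance + intercept + slope * std_concs
    analyte_conc = true_value * oil_concentration / 1.0  # ug/ml in the assay
    A_sample = blank_absorbance + intercept + slope * analyte_conc
    return AssayPlate(
        kind=kind,
        n_replicates=n_replicates,
        sample_absorbances=jitter(np.full(n_replicates, A_sample)),
        standard_concentrations=std_concs,
        standard_absorbances=std_abs,
        oil_concentration=oil_concentration,
        blank_absorbance=blank_absorbance,
    )


def simulate_abts_pair(
    teac_true: float,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    ec50_trolox: float = 4.0,
) -> tuple[AssayPlate, AssayPlate]:
    """Sample plate plus its matching Trolox standard plate.

    The standard plate is the ABTS dilution series of pure Trolox (mg/l)
    measured under the same conditions; analysing the pair with
    :func:`oilmark.bioassays.abts_analyze` recovers ``teac_true``.
    """
    sample = simulate_assay_plate(
        "ABTS", teac_true, noise_sd=noise_sd, n_replicates=n_replicates,
        seed=seed, ec50_trolox=ec50_trolox,
    )
    trolox = simulate_assay_plate(
        "ABTS", 1.0, noise_sd=noise_sd, n_replicates=n_replicates,
        seed=seed + 10_007, ec50_trolox=ec50_trolox,
    )
    return sample, trolox
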