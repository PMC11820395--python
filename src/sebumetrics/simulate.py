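"""Synthetic groomed-fingerprint cohorts.

Emits per-sample centroid MS1 spectra (and mzML) plus a metadata table with
the statistical structure the downstream analyses assume: per-donor baseline
lipid profiles over 250-1300 m/z, a region-specific intensity shift (neck
distinct from cheek/forehead by default), an optional sex effect (null by
default), multiplicative batch effects, per-sample total-lipid-load
variation, and ~3% multiplicative technical noise.

Two study designs are provided:

* :func:`simulate_cohort` — the variability design: ``n_donors`` donors, each
  contributing ``samples_per_donor_per_region`` fingerprints per grooming
  region (30 donors x 3 regions x 2 fingers = 180 samples by default).
* :func:`simulate_replicate_study` — the reproducibility design: one donor,
  six technical replicates per region, each replicate injected once into each
  of five MS batches (90 spectra).

Everything is a deterministic function of the config and its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .matrix import write_metadata
from .ms1 import CentroidSpectrum, write_ms1, write_mzml

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_replicate_study",
    "generate_cohort",
    "generate_replicate_study",
]

#: retention times (min) of the scans inside the 0.8-1.0 min injection plug
#: and the fraction of a sample's intensity carried by each
_IN_WINDOW_RTS = (0.82, 0.90, 0.98)
_IN_WINDOW_FRACTIONS = (0.3, 0.4, 0.3)
#: scans outside the window (exercise the RT filter); carry 5% of the
#: sample's intensity each and are excluded by binning
_OUT_WINDOW_RTS = (0.50, 1.30)
_OUT_WINDOW_SCALE = 0.05


@dataclass
class CohortConfig:
    """Parameters of a simulated fingerprint cohort.

    Effects are specified on the log2 scale and exponentiated into the
    emitted intensities; noise and batch drift are multiplicative on the
    linear scale, matching the %RSD metric's interpretation.
    """

    n_donors: int = 30
    samples_per_donor_per_region: int = 2
    regions: tuple[str, ...] = ("forehead", "cheek", "neck")
    n_lipid_peaks: int = 500
    #: region -> (fraction of peaks shifted, log2 fold change); regions not
    #: listed share the common baseline (cheek/forehead identical by default)
    region_effects: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"neck": (0.2, 1.0)}
    )
    sex_effect_size: float = 0.0  # log2 fold change, null by default
    sex_effect_fraction: float = 0.2
    donor_sd: float = 0.3  # between-donor log2 SD per peak
    n_batches: int = 6  # consecutive-block MS batches in the cohort design
    n_replicates: int = 6  # technical replicates (reproducibility design)
    n_injection_batches: int = 5  # repeat-injection batches (reproducibility)
    batch_multipliers: tuple[float, ...] | None = None  # global per-batch scale; 1.0 if None
    batch_peak_cv: float = 0.04  # per-peak per-batch multiplicative drift CV
    tic_sd: float = 0.25  # per-sample log-normal total-load SD (natural log)
    technical_cv: float = 0.03  # multiplicative noise CV per peak per injection
    rng_seed: int = 0

    def validate(self, n_batches_needed: int) -> None:
        if self.n_donors < 2:
            raise ConfigurationError("n_donors must be >= 2")
        if self.samples_per_donor_per_region < 1 or self.n_lipid_peaks < 1:
            raise ConfigurationError("counts must be positive")
        if not self.regions or len(set(self.regions)) != len(self.regions):
            raise ConfigurationError("regions must be a non-empty set of distinct labels")
        if self.technical_cv < 0 or self.tic_sd < 0 or self.donor_sd < 0 or self.batch_peak_cv < 0:
            raise ConfigurationError("noise magnitudes must be non-negative")
        for region in self.region_effects:
            if region not in self.regions:
                raise ConfigurationError(f"region effect for unknown region {region!r}")
        if self.batch_multipliers is not None and len(self.batch_multipliers) != n_batches_needed:
            raise ConfigurationError(
                f"batch_multipliers must have length {n_batches_needed}, "
                f"got {len(self.batch_multipliers)}"
            )


@dataclass
class SyntheticTruth:
    """The effects actually injected into a simulated cohort."""

    mz: np.ndarray  # per-peak m/z, Da, sorted
    baseline: np.ndarray  # per-peak baseline linear intensity
    region_effect_log2: dict[str, np.ndarray]  # per-peak log2 shift per region
    sex_effect_log2: np.ndarray  # per-peak log2 shift applied to male donors
    donor_offsets_log2: np.ndarray  # (n_donors, n_peaks)
    batch_multipliers: np.ndarray  # global per-batch scale factors
    batch_peak_factors: np.ndarray  # (n_batches, n_peaks) multiplicative drift
    tic_factors: dict[str, float]  # per physical sample total-load factor
    technical_cv: float = 0.0


@dataclass
class SimulatedCohort:
    """In-memory simulation result: spectra per sample, metadata, truth."""

    spectra: dict[str, list[CentroidSpectrum]]
    metadata: pd.DataFrame
    truth: SyntheticTruth
    config: CohortConfig

    def write(self, out_dir: str | Path, formats: Sequence[str] = ("ms1",)) -> dict[str, Path]:
        """Write one spectra file per sample plus ``metadata.tsv``.

        Returns a mapping sample_id -> path of the first requested format.
        """
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for sid, spectra in self.spectra.items():
            for fmt in formats:
                if fmt == "ms1":
                    p = out_dir / f"{sid}.ms1"
                    write_ms1(p, spectra)
                elif fmt == "mzml":
                    p = out_dir / f"{sid}.mzML"
                    write_mzml(p, spectra)
                else:
                    raise ConfigurationError(f"unknown spectra format {fmt!r}")
                paths.setdefault(sid, p)
        write_metadata(out_dir / "metadata.tsv", self.metadata)
        return paths


# ---------------------------------------------------------------------------


def _draw_peaks(cfg: CohortConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Distinct peak m/z values in [250, 1300) and log-normal baselines."""
    mz = np.round(rng.uniform(250.0, 1300.0, size=cfg.n_lipid_peaks), 4)
    mz = np.minimum(mz, 1300.0 - 1e-4)
    while len(np.unique(mz)) < cfg.n_lipid_peaks:  # resolve rounding collisions
        mz = np.unique(mz)
        extra = np.round(rng.uniform(250.0, 1300.0, size=cfg.n_lipid_peaks - len(mz)), 4)
        mz = np.concatenate([mz, np.minimum(extra, 1300.0 - 1e-4)])
    mz.sort()
    baseline = np.exp2(rng.normal(17.0, 2.0, size=cfg.n_lipid_peaks))
    return mz, baseline


def _draw_truth(cfg: CohortConfig, n_batches: int, rng: np.random.Generator) -> SyntheticTruth:
    mz, baseline = _draw_peaks(cfg, rng)
    n = cfg.n_lipid_peaks

    region_effect: dict[str, np.ndarray] = {}
    for region in cfg.regions:
        eff = np.zeros(n)
        if region in cfg.region_effects:
            frac, log2fc = cfg.region_effects[region]
            k = int(round(frac * n))
            idx = rng.choice(n, size=k, replace=False)
            eff[idx] = log2fc
        region_effect[region] = eff

    sex_eff = np.zeros(n)
    k = int(round(cfg.sex_effect_fraction * n))
    idx = rng.choice(n, size=k, replace=False)  # drawn regardless of size, for seed stability
    sex_eff[idx] = cfg.sex_effect_size

    donor_offsets = cfg.donor_sd * rng.standard_normal((cfg.n_donors, n))

    if cfg.batch_multipliers is None:
        multipliers = np.ones(n_batches)
    else:
        multipliers = np.asarray(cfg.batch_multipliers, dtype=float)
    batch_peak = np.exp(cfg.batch_peak_cv * rng.standard_normal((n_batches, n)))

    return SyntheticTruth(
        mz=mz,
        baseline=baseline,
        region_effect_log2=region_effect,
        sex_effect_log2=sex_eff,
        donor_offsets_log2=donor_offsets,
        batch_multipliers=multipliers,
        batch_peak_factors=batch_peak,
        tic_factors={},
        technical_cv=cfg.technical_cv,
    )


def _emit_spectra(amount: np.ndarray, mz: np.ndarray) -> list[CentroidSpectrum]:
    """Split a sample's per-peak intensities over the fixed scan structure.

    Emitted values are rounded to the MS1 text precision (4 decimals) so the
    MS1 and mzML renderings of a sample carry identical numbers.
    """
    scans = [
        CentroidSpectrum(rt, mz, np.round(amount * frac, 4))
        for rt, frac in zip(_IN_WINDOW_RTS, _IN_WINDOW_FRACTIONS)
    ]
    for rt in _OUT_WINDOW_RTS:
        scans.append(CentroidSpectrum(rt, mz, np.round(amount * _OUT_WINDOW_SCALE, 4)))
    scans.sort(key=lambda s: s.retention_time)
    return scans


def _noise_factor(cfg: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    z = rng.standard_normal(cfg.n_lipid_peaks)
    return np.clip(1.0 + cfg.technical_cv * z, 0.0, None)


def simulate_cohort(config: CohortConfig | None = None) -> SimulatedCohort:
    """Simulate the variability cohort (default 30 donors x 3 regions x 2).

    Sample intensities follow
    ``baseline * 2**(donor + region + sex) * batch * tic * (1 + noise)``
    truncated at zero, with the batch factor composed of the global batch
    multiplier and per-peak batch drift. Injection order is a seeded
    permutation; MS batches are consecutive blocks.
    """
    cfg = config or CohortConfig()
    cfg.validate(cfg.n_batches)
    rng = np.random.default_rng(cfg.rng_seed)
    truth = _draw_truth(cfg, cfg.n_batches, rng)

    rows = []
    for d in range(cfg.n_donors):
        sex = "male" if d % 2 == 0 else "female"
        for region in cfg.regions:
            for rep in range(1, cfg.samples_per_donor_per_region + 1):
                rows.append(
                    dict(
                        sample_id=f"D{d:02d}_{region}_{rep}",
                        donor_id=f"D{d:02d}",
                        sex=sex,
                        region=region,
                        replicate=rep,
                    )
                )
    meta = pd.DataFrame(rows)
    n_samples = len(meta)
    if n_samples % cfg.n_batches:
        raise ConfigurationError(
            f"{n_samples} samples do not divide into {cfg.n_batches} equal batches"
        )
    meta["injection_order"] = rng.permutation(n_samples) + 1
    block = n_samples // cfg.n_batches
    meta["batch"] = (meta["injection_order"] - 1) // block + 1

    spectra: dict[str, list[CentroidSpectrum]] = {}
    donor_index = {f"D{d:02d}": d for d in range(cfg.n_donors)}
    for row in meta.itertuples(index=False):
        tic = float(np.exp(cfg.tic_sd * rng.standard_normal()))
        truth.tic_factors[row.sample_id] = tic
        log2_shift = (
            truth.donor_offsets_log2[donor_index[row.donor_id]]
            + truth.region_effect_log2[row.region]
            + (truth.sex_effect_log2 if row.sex == "male" else 0.0)
        )
        b = row.batch - 1
        amount = (
            truth.baseline
            * np.exp2(log2_shift)
            * truth.batch_multipliers[b]
            * truth.batch_peak_factors[b]
            * tic
            * _noise_factor(cfg, rng)
        )
        spectra[row.sample_id] = _emit_spectra(amount, truth.mz)
    return SimulatedCohort(spectra, meta, truth, cfg)


def simulate_replicate_study(config: CohortConfig | None = None) -> SimulatedCohort:
    """Simulate the reproducibility design: one donor, six technical
    replicates per region, each injected once into each of five MS batches.

    Replicates share the donor's true profile (they are technical); each
    physical replicate carries its own total-load factor, constant across its
    injections, and every injected spectrum draws fresh technical noise and
    its batch's drift.
    """
    cfg = config or CohortConfig()
    cfg.validate(cfg.n_injection_batches)
    rng = np.random.default_rng(cfg.rng_seed)
    truth = _draw_truth(cfg, cfg.n_injection_batches, rng)
    donor_off = truth.donor_offsets_log2[0]

    # per-replicate total-load factors (the vial), per region
    rep_tic = {
        (region, rep): float(np.exp(cfg.tic_sd * rng.standard_normal()))
        for region in cfg.regions
        for rep in range(1, cfg.n_replicates + 1)
    }

    rows = []
    spectra: dict[str, list[CentroidSpectrum]] = {}
    injection = 0
    for batch in range(1, cfg.n_injection_batches + 1):
        for region in cfg.regions:
            for rep in range(1, cfg.n_replicates + 1):
                injection += 1
                sid = f"R{rep}_{region}_b{batch}"
                tic = rep_tic[(region, rep)]
                truth.tic_factors[sid] = tic
                amount = (
                    truth.baseline
                    * np.exp2(donor_off + truth.region_effect_log2[region])
                    * truth.batch_multipliers[batch - 1]
                    * truth.batch_peak_factors[batch - 1]
                    * tic
                    * _noise_factor(cfg, rng)
                )
                spectra[sid] = _emit_spectra(amount, truth.mz)
                rows.append(
                    dict(
                        sample_id=sid,
                        donor_id="D00",
                        sex="female",
                        region=region,
                        replicate=rep,
                        injection_order=injection,
                        batch=batch,
                    )
                )
    meta = pd.DataFrame(rows)
    return SimulatedCohort(spectra, meta, truth, cfg)


def generate_cohort(
    config: CohortConfig | None = None,
    out_dir: str | Path = ".",
    formats: Sequence[str] = ("ms1",),
) -> tuple[dict[str, Path], pd.DataFrame, SyntheticTruth]:
    """Simulate a cohort and write its MS1/mzML files and metadata TSV."""
    sim = simulate_cohort(config)
    paths = sim.write(out_dir, formats)
    return paths, sim.metadata, sim.truth


def generate_replicate_study(
    config: CohortConfig | None = None,
    out_dir: str | Path = ".",
    formats: Sequence[str] = ("ms1",),
) -> tuple[dict[str, Path], pd.DataFrame, SyntheticTruth]:
    """Simulate the replicate study and write its files and metadata TSV."""
    sim = simulate_replicate_study(config)
    paths = sim.write(out_dir, formats)
    return paths, sim.metadata, sim.truth
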