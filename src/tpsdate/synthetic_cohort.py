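"""Synthetic ancient-DNA cohorts with known ground truth.

Emulates the structure of a curated ancient-genomics compendium — samples
spanning ~0–10,000 years BP with high genotype missingness, family
clusters, country labels with coordinates, modern samples fixed at 10 BP —
while planting the exact signal the dating method exploits: per-component
allele-frequency profiles, a configurable share of SNPs with monotone
frequency trends over time, and per-sample component mixtures that vary
smoothly with true date.

The generator makes no attempt at coalescent realism, linkage, or
selection dynamics; only the frequency-over-time structure matters here.
Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    MISSING,
    MODERN_DATE_BP,
    DatingMethod,
    GenotypeMatrix,
    SampleRecord,
)
from .temporal_components import ComponentSet

__all__ = ["CohortSpec", "SyntheticCohort", "make_component_frequencies", "simulate_cohort"]

_DEFAULT_COUNTRIES: tuple[tuple[str, float, float], ...] = (
    ("Sweden", 59.3, 18.1),
    ("Germany", 51.2, 10.4),
    ("Spain", 40.4, -3.7),
    ("Italy", 41.9, 12.5),
    ("Turkey", 39.9, 32.9),
    ("Russia", 55.8, 37.6),
    ("Iran", 35.7, 51.4),
    ("China", 34.3, 108.9),
)


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort.

    Ancient epochs tile [10,000, 0] years BP in five 2,000-year blocks;
    three modern components share a recent epoch so they dominate at dates
    under ~500 BP. ``date_sd`` is drawn from a narrow/wide mixture so the
    date-uncertainty preprocessing filter has genuine outliers to remove,
    and a small fraction of ancient dates exceed 10,000 BP for the same
    reason. Country is drawn independently of date: geography is *not*
    confounded with time by construction.
    """

    n_samples: int = 800
    n_snps: int = 3000
    n_ancient_components: int = 5
    n_modern_components: int = 3
    ancient_epochs: tuple[tuple[float, float], ...] = (
        (10000.0, 8000.0),
        (8000.0, 6000.0),
        (6000.0, 4000.0),
        (4000.0, 2000.0),
        (2000.0, 0.0),
    )
    modern_epochs: tuple[tuple[float, float], ...] = ((500.0, 0.0),) * 3
    ancient_date_range: tuple[float, float] = (200.0, 9800.0)
    modern_frac: float = 0.25
    trend_fraction: float = 0.2
    trend_amplitude: tuple[float, float] = (0.1, 0.4)
    base_freq_range: tuple[float, float] = (0.05, 0.95)
    jitter: float = 0.02
    freq_clip: tuple[float, float] = (0.01, 0.99)
    missing_rate: float = 0.3
    modern_missing_rate: float = 0.0
    kernel_bandwidth: float = 1500.0
    n_families: int = 10
    family_size_range: tuple[int, int] = (2, 5)
    family_date_jitter: float = 0.0
    family_mode: str = "resample"            # or "copy"
    countries: tuple[tuple[str, float, float], ...] = _DEFAULT_COUNTRIES
    coord_jitter: float = 1.5
    date_sd_narrow: tuple[float, float] = (20.0, 100.0)
    date_sd_wide: tuple[float, float] = (300.0, 900.0)
    wide_sd_frac: float = 0.2
    context_method_frac: float = 0.25
    other_method_frac: float = 0.05
    old_outlier_frac: float = 0.02
    seed: int = 1

    def validate(self) -> None:
        if not 0.0 <= self.trend_fraction <= 1.0:
            raise ValueError("trend_fraction must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.kernel_bandwidth <= 0:
            raise ValueError("kernel bandwidth must be positive")
        lo, hi = self.trend_amplitude
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("trend amplitude range must sit inside [0, 1]")
        if len(self.ancient_epochs) != self.n_ancient_components:
            raise ValueError("one epoch per ancient component required")
        if len(self.modern_epochs) != self.n_modern_components:
            raise ValueError("one epoch per modern component required")
        spans = sorted(self.ancient_epochs, key=lambda e: -e[0])
        if spans[0][0] < 10000.0 or spans[-1][1] > 0.0:
            raise ValueError("ancient epochs must cover [0, 10000]")
        for (old_a, young_a), (old_b, _) in zip(spans, spans[1:]):
            if young_a > old_b:
                raise ValueError("ancient epochs leave a gap")


@dataclass
class SyntheticCohort:
    """A simulated cohort plus its complete ground truth."""

    matrix: GenotypeMatrix
    records: list[SampleRecord]
    truth: pd.DataFrame        # sample_id, true_date, family, w_<component>...
    components: ComponentSet
    snp_truth: pd.DataFrame    # snp_id, is_trend, direction, amplitude

    @property
    def true_weights(self) -> np.ndarray:
        cols = [c for c in self.truth.columns if c.startswith("w_")]
        return self.truth[cols].to_numpy()


def make_component_frequencies(
    spec: CohortSpec, seed: int | None = None
) -> tuple[ComponentSet, pd.DataFrame]:
    """Build per-component allele frequencies with planted trends.

    Trend SNPs get frequencies linear in the component's epoch *midpoint*
    (oldest to youngest), with total amplitude drawn uniformly from
    ``spec.trend_amplitude`` and a random direction, so the oldest-vs-
    youngest difference equals the drawn amplitude before clipping.
    Non-trend SNPs share one base frequency across components, plus small
    independent jitter. Everything is clipped to ``spec.freq_clip``.

    Returns the component set and a per-SNP truth table.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    K = spec.n_ancient_components + spec.n_modern_components
    m = spec.n_snps
    epochs = list(spec.ancient_epochs) + list(spec.modern_epochs)
    classes = ["ancient"] * spec.n_ancient_components + ["modern"] * spec.n_modern_components
    mids = np.array([(o + y) / 2.0 for o, y in epochs])
    # position 0 = oldest component, 1 = youngest
    t = (mids.max() - mids) / max(mids.max() - mids.min(), 1.0)

    n_trend = int(round(spec.trend_fraction * m))
    trend_idx = rng.choice(m, size=n_trend, replace=False)
    is_trend = np.zeros(m, dtype=bool)
    is_trend[trend_idx] = True

    base = rng.uniform(*spec.base_freq_range, size=m)
    amp = rng.uniform(*spec.trend_amplitude, size=m)
    direction = rng.choice([-1.0, 1.0], size=m)
    jit = rng.uniform(-spec.jitter, spec.jitter, size=(K, m))

    P = np.empty((K, m))
    # trend: straight line in epoch position; centered so the base is the midpoint
    line = (t[:, None] - 0.5) * (direction * amp)[None, :]
    P[:, is_trend] = base[None, is_trend] + line[:, is_trend]
    P[:, ~is_trend] = base[None, ~is_trend] + jit[:, ~is_trend]
    P = np.clip(P, *spec.freq_clip)

    comps = ComponentSet(
        ids=[f"{'anc' if c == 'ancient' else 'mod'}{i}" for i, c in enumerate(classes)],
        classes=classes,
        frequencies=P,
        epochs=epochs,
        snp_ids=[f"snp{j}" for j in range(m)],
        provenance=[{"fit": "synthetic", "seed": int(rng.bit_generator.seed_seq.entropy or 0)}
                    for _ in classes],
    )
    snp_truth = pd.DataFrame(
        {
            "snp_id": comps.snp_ids,
            "is_trend": is_trend,
            "direction": np.where(is_trend, np.where(direction > 0, "increasing", "decreasing"), "none"),
            "amplitude": np.where(is_trend, amp, 0.0),
        }
    ).set_index("snp_id")
    return comps, snp_truth


def _mixing_weights(dates: np.ndarray, mids: np.ndarray, bandwidth: float) -> np.ndarray:
    """Gaussian kernel over epoch midpoints, normalised per sample."""
    d2 = (dates[:, None] - mids[None, :]) ** 2
    W = np.exp(-0.5 * d2 / bandwidth**2)
    W = np.maximum(W, 1e-300)
    return W / W.sum(axis=1, keepdims=True)


def simulate_cohort(
    spec: CohortSpec,
    components: ComponentSet | None = None,
    seed: int | None = None,
) -> SyntheticCohort:
    """Simulate genotypes, metadata and ground truth for one cohort.

    Each sample draws a true date (ancient: uniform over the configured
    range, with a small old-outlier tail; modern: fixed at 10 BP), mixes
    the components with a Gaussian kernel on the date/epoch-midpoint
    distance, and draws genotypes Binomial(2, w @ P) per SNP. Families
    share their founder's date and mixing weights; members' genotypes are
    independently resampled (``family_mode="copy"`` duplicates the founder
    row instead, for the biased-duplicate robustness analysis). Country is
    assigned independently of date.
    """
    spec.validate()
    master = spec.seed if seed is None else seed
    rng = np.random.default_rng(master)
    if components is None:
        components, snp_truth = make_component_frequencies(spec, seed=master)
    else:
        _, snp_truth = make_component_frequencies(spec, seed=master)

    n = spec.n_samples
    n_modern = int(round(spec.modern_frac * n))
    n_ancient = n - n_modern

    dates = np.empty(n)
    dates[:n_ancient] = rng.uniform(*spec.ancient_date_range, size=n_ancient)
    n_old = int(round(spec.old_outlier_frac * n_ancient))
    if n_old:
        old_rows = rng.choice(n_ancient, size=n_old, replace=False)
        dates[old_rows] = rng.uniform(10000.0, 14000.0, size=n_old)
    dates[n_ancient:] = MODERN_DATE_BP
    is_ancient = np.zeros(n, dtype=bool)
    is_ancient[:n_ancient] = True

    # families among ancient samples: founders + following rows become kin
    family_id = np.array([None] * n, dtype=object)
    founder_of = np.full(n, -1, dtype=int)
    cursor = 0
    for f in range(spec.n_families):
        size = int(rng.integers(spec.family_size_range[0], spec.family_size_range[1] + 1))
        if cursor + size > n_ancient:
            break
        rows = np.arange(cursor, cursor + size)
        family_id[rows] = f"fam{f}"
        founder_of[rows] = rows[0]
        jitter = rng.normal(0.0, spec.family_date_jitter, size=size - 1) if spec.family_date_jitter else 0.0
        dates[rows[1:]] = np.clip(dates[rows[0]] + jitter, 0.0, 14000.0)
        cursor += size

    mids = components.epoch_midpoints()
    W = _mixing_weights(dates, mids, spec.kernel_bandwidth)

    F = W @ components.frequencies              # per-sample expected frequency
    calls = rng.binomial(2, np.clip(F, 0.0, 1.0)).astype(np.int8)
    if spec.family_mode == "copy":
        for i in range(n):
            if founder_of[i] >= 0 and founder_of[i] != i:
                calls[i] = calls[founder_of[i]]
    elif spec.family_mode != "resample":
        raise ValueError(f"unknown family_mode {spec.family_mode!r}")

    miss_p = np.where(is_ancient, spec.missing_rate, spec.modern_missing_rate)
    miss = rng.random(size=calls.shape) < miss_p[:, None]
    calls[miss] = MISSING

    country_idx = rng.integers(len(spec.countries), size=n)
    lat = np.array([spec.countries[c][1] for c in country_idx]) + rng.normal(
        0, spec.coord_jitter, size=n
    )
    lon = np.array([spec.countries[c][2] for c in country_idx]) + rng.normal(
        0, spec.coord_jitter, size=n
    )

    wide = rng.random(n) < spec.wide_sd_frac
    date_sd = np.where(
        wide,
        rng.uniform(*spec.date_sd_wide, size=n),
        rng.uniform(*spec.date_sd_narrow, size=n),
    )
    date_sd[~is_ancient] = 0.0

    u = rng.random(n)
    methods = np.where(
        u < spec.other_method_frac,
        DatingMethod.OTHER.value,
        np.where(
            u < spec.other_method_frac + spec.context_method_frac,
            DatingMethod.ARCHAEOLOGICAL_CONTEXT.value,
            DatingMethod.RADIOCARBON_DIRECT.value,
        ),
    )
    methods[~is_ancient] = DatingMethod.MODERN.value

    sample_ids = [f"S{i:05d}" for i in range(n)]
    records = [
        SampleRecord(
            sample_id=sample_ids[i],
            date_mean=float(dates[i]) if is_ancient[i] else MODERN_DATE_BP,
            date_sd=float(date_sd[i]),
            dating_method=DatingMethod(methods[i]),
            country=spec.countries[country_idx[i]][0],
            latitude=float(lat[i]),
            longitude=float(lon[i]),
            family_id=family_id[i],
        )
        for i in range(n)
    ]

    matrix = GenotypeMatrix(
        sample_ids=sample_ids,
        snp_ids=list(components.snp_ids or [f"snp{j}" for j in range(spec.n_snps)]),
        calls=calls,
    )
    matrix.validate()

    truth = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "true_date": dates,
            "family": family_id,
        }
    )
    for k, cid in enumerate(components.ids):
        truth[f"w_{cid}"] = W[:, k]
    truth = truth.set_index("sample_id")

    return SyntheticCohort(
        matrix=matrix,
        records=records,
        truth=truth,
        components=components,
        snp_truth=snp_truth,
    )
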