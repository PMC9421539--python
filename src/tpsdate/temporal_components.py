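"""Temporal-component curation.

A temporal component is an admixture component whose prevalence peaks in a
delimited historical period rather than a geographic region. This module
scores candidate components for temporality (replacing a visual selection
with a reproducible statistic), generates synthetic reference genomes per
component, assigns each ancient component a date range (epoch), and
produces the per-sample 8-component profiles that feed the dating model.

Component order is fixed throughout the package: ancient components sorted
oldest to youngest by epoch midpoint, then modern components. "First
ancient component" downstream always means the oldest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import admixture_engine as adm
from .io_formats import GenotypeMatrix, SampleRecord

__all__ = [
    "ComponentSet",
    "ComponentProfile",
    "TemporalityScore",
    "temporality_score",
    "generate_component_genomes",
    "assign_epochs",
    "build_profiles",
    "select_columns",
    "curate_components",
]


@dataclass
class ComponentSet:
    """K allele-frequency vectors, each with a class and a date range.

    ``epochs[k]`` is ``(old_bound, young_bound)`` in years BP with
    ``old >= young``; ancient epochs live within [0, 10000]. ``provenance``
    records which fit and column each component came from.
    """

    ids: list[str]
    classes: list[str]                     # "ancient" | "modern"
    frequencies: np.ndarray                # (K, n_snps)
    epochs: list[tuple[float, float]]
    snp_ids: list[str] | None = None
    provenance: list[dict] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.ids)

    @property
    def ancient_index(self) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.classes) if c == "ancient"])

    @property
    def modern_index(self) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.classes) if c == "modern"])

    def epoch_midpoints(self) -> np.ndarray:
        return np.array([(o + y) / 2.0 for o, y in self.epochs])

    def sorted_old_to_young(self) -> "ComponentSet":
        """Canonical order: ancient oldest -> youngest, then modern."""
        anc = sorted(
            self.ancient_index,
            key=lambda i: (-self.epoch_midpoints()[i], -self.epochs[i][0]),
        )
        order = list(anc) + list(self.modern_index)
        return ComponentSet(
            ids=[self.ids[i] for i in order],
            classes=[self.classes[i] for i in order],
            frequencies=self.frequencies[order].copy(),
            epochs=[self.epochs[i] for i in order],
            snp_ids=self.snp_ids,
            provenance=[self.provenance[i] for i in order] if self.provenance else [],
        )

    def validate(self) -> None:
        K = self.n_components
        if not (len(self.classes) == K == self.frequencies.shape[0] == len(self.epochs)):
            raise ValueError("component fields disagree in length")
        if ((self.frequencies < 0) | (self.frequencies > 1)).any():
            raise ValueError("component frequencies outside [0, 1]")
        for i in self.ancient_index:
            old, young = self.epochs[i]
            if not (10000 >= old >= young >= 0):
                raise ValueError(f"ancient epoch {self.epochs[i]} outside [0, 10000]")


@dataclass
class ComponentProfile:
    """A sample's mixing fractions over the ordered components; sums to 1."""

    sample_id: str
    q: np.ndarray

    def validate(self) -> None:
        if abs(float(self.q.sum()) - 1.0) > 1e-6:
            raise ValueError(f"{self.sample_id}: profile does not sum to 1")


@dataclass
class TemporalityScore:
    rho: float          # |Spearman| of per-bin mean fraction vs bin index
    geo_ratio: float    # between-country / total variance in the peak bin
    n_bins: int
    passes: bool


def temporality_score(
    q_column: np.ndarray,
    dates: np.ndarray,
    countries: Sequence[str],
    bin_years: float = 500.0,
    min_bin_size: int = 5,
    rho_threshold: float = 0.5,
    geo_threshold: float = 0.5,
) -> TemporalityScore:
    """Score one component for temporal (vs geographic) structure.

    Dates are binned into ``bin_years`` epochs; bins with at least
    ``min_bin_size`` samples contribute their mean component fraction to a
    Spearman correlation against bin index. The geography diagnostic is the
    between-country share of the component's variance inside its peak bin.
    A candidate passes with |rho| >= ``rho_threshold`` and geography ratio
    <= ``geo_threshold``.
    """
    q_column = np.asarray(q_column, dtype=float)
    dates = np.asarray(dates, dtype=float)
    countries = np.asarray(countries)
    bins = np.floor(dates / bin_years).astype(int)

    uniq, counts = np.unique(bins, return_counts=True)
    eligible = uniq[counts >= min_bin_size]
    if len(eligible) < 3:
        raise ValueError(
            f"temporality score undefined: only {len(eligible)} bins with "
            f">= {min_bin_size} samples"
        )
    bin_means = np.array([q_column[bins == b].mean() for b in eligible])
    if np.allclose(bin_means, bin_means[0]):
        rho = 0.0
    else:
        rho = abs(float(stats.spearmanr(eligible, bin_means).statistic))

    peak_bin = eligible[int(np.argmax(bin_means))]
    in_peak = bins == peak_bin
    x = q_column[in_peak]
    c = countries[in_peak]
    ss_total = float(((x - x.mean()) ** 2).sum())
    if ss_total == 0:
        geo_ratio = 0.0
    else:
        ss_between = 0.0
        for country in np.unique(c):
            sel = x[c == country]
            ss_between += len(sel) * (sel.mean() - x.mean()) ** 2
        geo_ratio = float(ss_between / ss_total)

    return TemporalityScore(
        rho=rho,
        geo_ratio=geo_ratio,
        n_bins=len(eligible),
        passes=(rho >= rho_threshold) and (geo_ratio <= geo_threshold),
    )


def generate_component_genomes(
    frequencies: np.ndarray,
    n: int = 15,
    seed: int = 0,
    component_id: str = "comp",
    snp_ids: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Draw ``n`` synthetic reference genomes from one component.

    Genotypes are independent Binomial(2, p_j) draws; no missingness.
    Sample ids are tagged with the component id.
    """
    if n < 1:
        raise ValueError("need n >= 1 synthetic genomes")
    p = np.asarray(frequencies, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("frequencies outside [0, 1]")
    rng = np.random.default_rng(seed)
    calls = rng.binomial(2, p[None, :], size=(n, p.size)).astype(np.int8)
    m = p.size
    return GenotypeMatrix(
        sample_ids=[f"{component_id}_syn{i}" for i in range(n)],
        snp_ids=list(snp_ids) if snp_ids is not None else [f"snp{j}" for j in range(m)],
        calls=calls,
    )


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: float) -> float:
    """Weighted quantile with linear interpolation (midpoint positions)."""
    order = np.argsort(x)
    x, w = x[order], w[order]
    cw = np.cumsum(w)
    total = cw[-1]
    positions = (cw - 0.5 * w) / total
    return float(np.interp(q, positions, x))


def assign_epochs(
    profiles: np.ndarray,
    dates: np.ndarray,
    mass: float = 0.90,
    bin_years: float = 500.0,
) -> list[tuple[float, float]]:
    """Assign each component the date range holding ``mass`` of its weight.

    For each profile column the epoch is the weighted (1-mass)/2 .. 1-(1-mass)/2
    quantile interval of sample dates, weights being the samples' component
    fractions, with end points snapped *outward* to ``bin_years`` edges.
    """
    profiles = np.asarray(profiles, dtype=float)
    dates = np.asarray(dates, dtype=float)
    lo_q = (1.0 - mass) / 2.0
    epochs: list[tuple[float, float]] = []
    for k in range(profiles.shape[1]):
        w = profiles[:, k]
        if w.sum() <= 0:
            raise ValueError(f"component column {k} has zero total weight")
        young = _weighted_quantile(dates, w, lo_q)
        old = _weighted_quantile(dates, w, 1.0 - lo_q)
        old = float(np.ceil(old / bin_years) * bin_years)
        young = float(np.floor(young / bin_years) * bin_years)
        epochs.append((old, young))
    return epochs


def build_profiles(
    G_all: GenotypeMatrix,
    component_genomes: dict[str, GenotypeMatrix],
    component_order: Sequence[str] | None = None,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 300,
    p_from_labels_only: bool = False,
) -> tuple[pd.DataFrame, adm.AdmixtureFit]:
    """Project all samples against labelled synthetic component genomes.

    Stacks the reference genomes with the cohort, runs the supervised fit,
    and returns the cohort rows of Q as a DataFrame (samples x components,
    columns in ``component_order``) plus the full fit (whose P is the
    components' refined allele-frequency matrix). Every sample receives a
    complete profile — the output has no missing values.
    """
    order = list(component_order) if component_order else sorted(component_genomes)
    K = len(order)
    ref_calls = np.vstack([component_genomes[c].calls for c in order])
    labels: dict[int, int] = {}
    row = 0
    for k, cid in enumerate(order):
        n_ref = component_genomes[cid].calls.shape[0]
        for _ in range(n_ref):
            labels[row] = k
            row += 1
    stacked = np.vstack([ref_calls, G_all.calls])
    labels = dict(labels)  # reference rows come first
    fit = adm.fit_supervised(
        stacked, labels, K, seed=seed, tol=tol, max_iter=max_iter,
        p_from_labels_only=p_from_labels_only,
    )
    Q_cohort = fit.Q[row:, :]
    df = pd.DataFrame(Q_cohort, index=list(G_all.sample_ids), columns=order)
    df.index.name = "sample_id"
    return df, fit


def select_columns(
    Q: np.ndarray,
    dates: np.ndarray,
    countries: Sequence[str],
    is_ancient: np.ndarray | None = None,
    n_ancient: int = 5,
    n_modern: int = 3,
    ancient_min_mean_date: float = 1000.0,
    corr_threshold: float = 0.95,
    rho_threshold: float = 0.5,
    geo_threshold: float = 0.5,
    manual_override: Sequence[int] | None = None,
) -> tuple[list[int], list[str], list[TemporalityScore | None]]:
    """Pick candidate temporal components from an unsupervised Q.

    Columns are classed ancient/modern by how strongly they load on modern
    samples: the ``n_modern`` columns most enriched in modern individuals
    are the modern candidates (falling back to a weighted-mean-date
    threshold when no modern flags are supplied). Candidates are scored
    with :func:`temporality_score`, de-duplicated at pairwise correlation
    ``corr_threshold`` (the lower-scoring duplicate drops), and the top
    ``n_ancient`` + ``n_modern`` by |rho| retained per class, passing
    candidates first. ``manual_override`` short-circuits selection with
    explicit column indices (the audited escape hatch for a curation that
    remains irreducibly judgement-based).
    """
    Q = np.asarray(Q, dtype=float)
    K = Q.shape[1]
    if is_ancient is not None and (~np.asarray(is_ancient)).any():
        anc = np.asarray(is_ancient, dtype=bool)
        enrich = np.array(
            [
                Q[~anc, k].mean() / max(Q[~anc, k].mean() + Q[anc, k].mean(), 1e-12)
                for k in range(K)
            ]
        )
        modern_cols = set(np.argsort(-enrich)[:n_modern])
        classes_all = ["modern" if k in modern_cols else "ancient" for k in range(K)]
    else:
        wmean = np.array(
            [float((Q[:, k] * dates).sum() / max(Q[:, k].sum(), 1e-12)) for k in range(K)]
        )
        classes_all = ["ancient" if w > ancient_min_mean_date else "modern" for w in wmean]

    scores: list[TemporalityScore | None] = []
    for k in range(K):
        try:
            scores.append(
                temporality_score(
                    Q[:, k], dates, countries,
                    rho_threshold=rho_threshold, geo_threshold=geo_threshold,
                )
            )
        except ValueError:
            scores.append(None)

    if manual_override is not None:
        chosen = list(manual_override)
        return chosen, [classes_all[k] for k in chosen], scores

    def sort_key(k: int):
        s = scores[k]
        if s is None:
            return (1, 1, 0.0)
        return (0, 0 if s.passes else 1, -s.rho)

    # drop near-duplicate columns (keep the better-scoring one)
    alive = set(range(K))
    if K > 1:
        corr = np.corrcoef(Q.T)
        for a in range(K):
            for b in range(a + 1, K):
                if a in alive and b in alive and abs(corr[a, b]) > corr_threshold:
                    alive.discard(max((a, b), key=lambda k: sort_key(k)))

    chosen: list[int] = []
    for cls, want in (("ancient", n_ancient), ("modern", n_modern)):
        pool = sorted(
            (k for k in alive if classes_all[k] == cls), key=sort_key
        )
        chosen.extend(pool[:want])
    # backfill from whatever remains if a class came up short
    if len(chosen) < n_ancient + n_modern:
        rest = sorted((k for k in alive if k not in chosen), key=sort_key)
        chosen.extend(rest[: n_ancient + n_modern - len(chosen)])
    chosen.sort()
    return chosen, [classes_all[k] for k in chosen], scores


def curate_components(
    G: GenotypeMatrix,
    records: Sequence[SampleRecord],
    n_ancient: int = 5,
    n_modern: int = 3,
    K: int | None = None,
    subsample_ancient: int = 300,
    subsample_modern: int = 250,
    n_synthetic: int = 15,
    seed: int = 0,
    epoch_mass: float = 0.90,
    rho_threshold: float = 0.5,
    geo_threshold: float = 0.5,
    unsupervised_kwargs: dict | None = None,
    supervised_kwargs: dict | None = None,
) -> tuple[ComponentSet, pd.DataFrame]:
    """Full component-curation pass: discover, select, project, date.

    1. unsupervised fit on a seeded random subsample (ancient + modern);
    2. score/select candidate columns for temporality;
    3. generate ``n_synthetic`` reference genomes per selected component;
    4. supervised projection of the whole cohort against the references;
    5. epoch assignment from the resulting profiles, components reordered
       oldest-to-youngest (ancient) then modern.

    Returns the curated :class:`ComponentSet` (frequencies taken from the
    supervised fit's P) and the cohort profiles aligned to its order.
    """
    if K is None:
        K = n_ancient + n_modern
    rng = np.random.default_rng(seed)
    by_id = {r.sample_id: r for r in records}
    recs = [by_id[s] for s in G.sample_ids]
    dates = np.array([r.date_mean for r in recs])
    countries = [r.country for r in recs]
    anc_rows = np.array([i for i, r in enumerate(recs) if r.is_ancient])
    mod_rows = np.array([i for i, r in enumerate(recs) if not r.is_ancient])

    take_anc = rng.choice(anc_rows, size=min(subsample_ancient, len(anc_rows)), replace=False)
    take_mod = (
        rng.choice(mod_rows, size=min(subsample_modern, len(mod_rows)), replace=False)
        if len(mod_rows)
        else np.empty(0, dtype=int)
    )
    sub = np.sort(np.concatenate([take_anc, take_mod]))

    unsup = adm.fit_unsupervised(
        G.calls[sub], K, seed=seed, **(unsupervised_kwargs or {})
    )
    chosen, classes, scores = select_columns(
        unsup.Q, dates[sub], [countries[i] for i in sub],
        is_ancient=np.array([recs[i].is_ancient for i in sub]),
        n_ancient=n_ancient, n_modern=n_modern,
        rho_threshold=rho_threshold, geo_threshold=geo_threshold,
    )

    comp_ids = [f"{'anc' if c == 'ancient' else 'mod'}_k{k}" for k, c in zip(chosen, classes)]
    genomes = {
        cid: generate_component_genomes(
            unsup.P[k], n=n_synthetic,
            seed=int(rng.integers(2**31)), component_id=cid,
            snp_ids=G.snp_ids,
        )
        for cid, k in zip(comp_ids, chosen)
    }
    profiles, sup_fit = build_profiles(
        G, genomes, component_order=comp_ids,
        seed=int(rng.integers(2**31)), **(supervised_kwargs or {}),
    )

    # epochs from dated ancient samples only; modern components span [500, 0]
    anc_cols = [i for i, c in enumerate(classes) if c == "ancient"]
    anc_profiles = profiles.to_numpy()[anc_rows][:, anc_cols]
    anc_epochs = assign_epochs(anc_profiles, dates[anc_rows], mass=epoch_mass)
    anc_epochs = [(min(o, 10000.0), max(y, 0.0)) for o, y in anc_epochs]
    epochs: list[tuple[float, float]] = []
    it = iter(anc_epochs)
    for c in classes:
        epochs.append(next(it) if c == "ancient" else (500.0, 0.0))

    comps = ComponentSet(
        ids=comp_ids,
        classes=classes,
        frequencies=sup_fit.P,
        epochs=epochs,
        snp_ids=list(G.snp_ids),
        provenance=[
            {"fit": "unsupervised", "seed": seed, "column": int(k),
             "rho": None if scores[k] is None else scores[k].rho}
            for k in chosen
        ],
    ).sorted_old_to_young()
    profiles = profiles[comps.ids]
    return comps, profiles
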