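"""Virtual species generation.

A virtual vertebrate species couples (i) a climatic niche sampled from a
niche-source table (body mass plus monthly temperature/precipitation samples
from its home region), (ii) trophic attributes transferred from a real-shaped
trophic table by body-size matching within the same taxon, (iii) a random
phenotype string whose pairwise compatibility (through a 26x26 trait matrix)
later decides which trophic links form, and (iv) an adaptive capacity used by
the acclimation mechanism.

The taxon tag (mammal/bird/reptile/amphibian) is latent: after trophic
assignment it is used *only* to look up taxon-pair-specific body-mass-ratio
limits during web assembly, never for niches, extinction or reporting.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .niche import NicheAxis, fit_axis, params_array

__all__ = [
    "TAXA",
    "ALPHABET",
    "VirtualSpecies",
    "TraitMatrix",
    "RatioLimits",
    "SpeciesPool",
    "body_sizes_match",
    "assign_trophic",
    "make_trait_matrix",
    "phenotype_compatibility",
    "derive_ratio_limits",
    "make_species_pool",
]

log = logging.getLogger(__name__)

TAXA = ("mammal", "bird", "reptile", "amphibian")
TAXON_INDEX = {t: i for i, t in enumerate(TAXA)}
ALPHABET = string.ascii_lowercase
N_LETTERS = 26
MAX_PHENOTYPE_LEN = 10

#: trophic level of the non-depletable plant/invertebrate resource pool.
#: A species whose trophic breadth floor reaches this level can feed on it
#: and is therefore "basal" (immune to bottom-up coextinction).
BASAL_RESOURCE_LEVEL = 0.0

MATCH_START = 0.01
MATCH_STEP = 0.01


@dataclass
class VirtualSpecies:
    id: int
    taxon: str
    body_mass: float  # grams
    trophic_level: float = 1.0
    trophic_breadth_floor: float = 0.0
    basal: bool = True
    phenotype: str = "a"
    adaptive_capacity: float = 0.0
    niche_T: NicheAxis | None = None
    niche_P: NicheAxis | None = None
    match_threshold: float = float("nan")  # final r_thresh used in matching

    def __post_init__(self):
        if self.body_mass <= 0:
            raise ValueError("body_mass must be positive")
        if not 1 <= len(self.phenotype) <= MAX_PHENOTYPE_LEN:
            raise ValueError("phenotype length must be in [1, 10]")


@dataclass
class TraitMatrix:
    """26x26 letter-by-letter compatibility with normalization constants.

    Raw phenotype scores are min-max normalized with ``norm_min``/``norm_max``
    estimated by scoring a large sample of random phenotype pairs; estimates
    are Monte-Carlo so out-of-range raw scores are clipped into [0, 1].
    """

    M: np.ndarray
    norm_min: float
    norm_max: float

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=float)
        if self.M.shape != (N_LETTERS, N_LETTERS):
            raise ValueError("trait matrix must be 26x26")
        if not self.norm_min < self.norm_max:
            raise ValueError(
                "degenerate trait matrix: normalization constants coincide"
            )


@dataclass
class RatioLimits:
    """Admissible resource:consumer body-mass-ratio windows per taxon pair.

    ``ll``/``lu`` are (4, 4) arrays indexed [resource_taxon, consumer_taxon]
    holding the 5th / 95th percentile of the observed ratio distribution.
    Pairs with fewer records than the minimum fall back to the pooled
    distribution; degenerate (zero-width) windows are widened by machine
    epsilon and flagged.
    """

    ll: np.ndarray
    lu: np.ndarray
    pooled: tuple[float, float]
    fallback_pairs: list = field(default_factory=list)
    degenerate_pairs: list = field(default_factory=list)

    def lookup(self, resource_taxon: str, consumer_taxon: str) -> tuple[float, float]:
        i, j = TAXON_INDEX[resource_taxon], TAXON_INDEX[consumer_taxon]
        return float(self.ll[i, j]), float(self.lu[i, j])


def body_sizes_match(m1: float, m2: float, r_thresh: float) -> bool:
    """Relative-difference body-size match rule."""
    if m1 <= 0 or m2 <= 0:
        raise ValueError("body masses must be positive")
    if not 0 < r_thresh <= 1:
        raise ValueError("r_thresh must lie in (0, 1]")
    hi, lo = max(m1, m2), min(m1, m2)
    return (hi - lo) / hi < r_thresh


def _relative_diff(mass: float, candidates: np.ndarray) -> np.ndarray:
    hi = np.maximum(mass, candidates)
    lo = np.minimum(mass, candidates)
    return (hi - lo) / hi


def assign_trophic(
    mass: float,
    taxon: str,
    trophic_table: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[float, float, float]:
    """Transfer trophic level and breadth floor by body-size matching.

    Candidates of the same taxon are scanned in random order at
    ``r_thresh = 0.01``; if none matches the threshold is raised by 0.01 and
    the scan repeated until a match emerges.  Equivalent (and implemented as):
    find the first escalation step admitting at least one candidate, then pick
    uniformly among the candidates admitted at that step.

    Returns (trophic_level, trophic_breadth_floor, final_threshold).
    """
    sub = trophic_table[trophic_table["taxon"] == taxon]
    if sub.empty:
        raise ValueError(f"trophic table has no records for taxon {taxon!r}")
    diffs = _relative_diff(mass, sub["mass"].to_numpy(dtype=float))
    # first threshold 0.01*k strictly above the closest candidate's difference
    k = int(np.floor(diffs.min() / MATCH_STEP)) + 1
    r_final = k * MATCH_STEP
    matched = np.flatnonzero(diffs < r_final)
    pick = int(rng.choice(matched))
    row = sub.iloc[pick]
    return float(row["trophic_level"]), float(row["breadth_floor"]), r_final


def random_phenotypes(n: int, rng: np.random.Generator) -> list[str]:
    """Random phenotype strings: length uniform on 1..10, letters uniform."""
    lengths = rng.integers(1, MAX_PHENOTYPE_LEN + 1, size=n)
    letters = rng.integers(0, N_LETTERS, size=int(lengths.sum()))
    out, pos = [], 0
    for L in lengths:
        out.append("".join(ALPHABET[i] for i in letters[pos : pos + L]))
        pos += L
    return out


def _random_counts(n: int, rng: np.random.Generator) -> np.ndarray:
    """Letter-count vectors of n random phenotypes, shape (n, 26)."""
    lengths = rng.integers(1, MAX_PHENOTYPE_LEN + 1, size=n)
    letters = rng.integers(0, N_LETTERS, size=(n, MAX_PHENOTYPE_LEN))
    mask = np.arange(MAX_PHENOTYPE_LEN) < lengths[:, None]
    counts = np.zeros((n, N_LETTERS), dtype=np.float64)
    rows = np.repeat(np.arange(n), lengths)
    np.add.at(counts, (rows, letters[mask]), 1.0)
    return counts


def phenotype_counts(ph: str) -> np.ndarray:
    counts = np.zeros(N_LETTERS, dtype=float)
    for ch in ph:
        i = ord(ch) - ord("a")
        if not 0 <= i < N_LETTERS:
            raise ValueError(f"phenotype letter {ch!r} outside the 26-letter alphabet")
        counts[i] += 1.0
    return counts


def make_trait_matrix(
    rng: np.random.Generator, n_pairs: int = 1_000_000
) -> TraitMatrix:
    """Draw a uniform 26x26 trait matrix and estimate normalization constants
    by scoring ``n_pairs`` random phenotype pairs (generated exactly as in
    species creation)."""
    M = rng.uniform(-1.0, 1.0, size=(N_LETTERS, N_LETTERS))
    norm_min, norm_max = np.inf, -np.inf
    chunk = 100_000
    done = 0
    while done < n_pairs:
        m = min(chunk, n_pairs - done)
        c1 = _random_counts(m, rng)
        c2 = _random_counts(m, rng)
        raw = np.einsum("ij,jk,ik->i", c1, M, c2)
        norm_min = min(norm_min, float(raw.min()))
        norm_max = max(norm_max, float(raw.max()))
        done += m
    return TraitMatrix(M, norm_min, norm_max)


def raw_compatibility(ph1: str, ph2: str, tm: TraitMatrix) -> float:
    """Un-normalized score: sum of M[l1, l2] over all ordered letter pairs
    (resource letters index rows, consumer letters index columns)."""
    return float(phenotype_counts(ph1) @ tm.M @ phenotype_counts(ph2))


def phenotype_compatibility(ph1: str, ph2: str, tm: TraitMatrix) -> float:
    raw = raw_compatibility(ph1, ph2, tm)
    return float(
        np.clip((raw - tm.norm_min) / (tm.norm_max - tm.norm_min), 0.0, 1.0)
    )


def derive_ratio_limits(
    interaction_records: pd.DataFrame, min_records: int = 20
) -> RatioLimits:
    """Central-90% body-mass-ratio windows per (resource, consumer) taxon pair.

    Columns required: resource_taxon, resource_mass, consumer_taxon,
    consumer_mass.
    """
    if interaction_records.empty:
        raise ValueError("interaction records are empty")
    rec = interaction_records
    ratios_all = rec["resource_mass"].to_numpy(dtype=float) / rec[
        "consumer_mass"
    ].to_numpy(dtype=float)
    pooled = tuple(np.quantile(ratios_all, [0.05, 0.95]))

    ll = np.full((4, 4), pooled[0])
    lu = np.full((4, 4), pooled[1])
    fallback, degenerate = [], []
    grouped = rec.groupby(["resource_taxon", "consumer_taxon"], sort=True)
    sizes = {pair: len(g) for pair, g in grouped}
    for rt in TAXA:
        for ct in TAXA:
            n = sizes.get((rt, ct), 0)
            if n < min_records:
                fallback.append((rt, ct))
                continue
            g = grouped.get_group((rt, ct))
            r = g["resource_mass"].to_numpy(dtype=float) / g[
                "consumer_mass"
            ].to_numpy(dtype=float)
            lo, hi = np.quantile(r, [0.05, 0.95])
            if lo == hi:  # zero-width window: widen by machine epsilon
                eps = max(abs(lo), 1.0) * np.finfo(float).eps
                lo, hi = lo - eps, hi + eps
                degenerate.append((rt, ct))
            i, j = TAXON_INDEX[rt], TAXON_INDEX[ct]
            ll[i, j], lu[i, j] = lo, hi
    return RatioLimits(ll, lu, pooled, fallback, degenerate)


@dataclass
class SpeciesPool:
    """A pool of virtual species plus packed arrays for the simulation.

    The arrays are column views of the species list: ``mass``, ``tl``
    (trophic level), ``floor`` (trophic breadth floor), ``basal``,
    ``taxon_idx``, ``adaptive``, ``counts`` (letter counts, n x 26) and the
    packed niche parameter arrays ``nT``/``nP`` (n x 7).
    """

    species: list[VirtualSpecies]
    mass: np.ndarray
    tl: np.ndarray
    floor: np.ndarray
    basal: np.ndarray
    taxon_idx: np.ndarray
    adaptive: np.ndarray
    counts: np.ndarray
    nT: np.ndarray
    nP: np.ndarray

    def __len__(self):
        return len(self.species)

    def to_frame(self) -> pd.DataFrame:
        """Serialize the pool to one row per species, niche parameters inline."""
        rows = []
        for sp in self.species:
            row = {
                "id": sp.id,
                "taxon": sp.taxon,
                "body_mass": sp.body_mass,
                "trophic_level": sp.trophic_level,
                "trophic_breadth_floor": sp.trophic_breadth_floor,
                "basal": sp.basal,
                "phenotype": sp.phenotype,
                "adaptive_capacity": sp.adaptive_capacity,
                "match_threshold": sp.match_threshold,
            }
            for tag, ax in (("T", sp.niche_T), ("P", sp.niche_P)):
                for f in ("x_mean", "v_min", "v_max", "a", "b", "c", "d"):
                    row[f"{tag}_{f}"] = getattr(ax, f)
            rows.append(row)
        return pd.DataFrame(rows)


def make_species_pool(
    niche_table: pd.DataFrame,
    trophic_table: pd.DataFrame,
    counts_per_taxon: dict[str, int],
    rng: np.random.Generator,
    p_thresh: float = 0.95,
) -> SpeciesPool:
    """Sample virtual species per taxon from the niche-source table.

    ``niche_table`` columns: taxon, mass, samples_T, samples_P (the sample
    columns hold per-species arrays of monthly climate values from the
    species' home region).  Requesting more species than a taxon's table rows
    falls back to sampling with replacement (logged as a warning).
    """
    species: list[VirtualSpecies] = []
    sid = 0
    for taxon in TAXA:
        want = int(counts_per_taxon.get(taxon, 0))
        if want == 0:
            continue
        sub = niche_table[niche_table["taxon"] == taxon]
        if sub.empty:
            raise ValueError(f"niche table has no records for taxon {taxon!r}")
        replace = want > len(sub)
        if replace:
            log.warning(
                "taxon %s: requested %d species from %d records; sampling with replacement",
                taxon,
                want,
                len(sub),
            )
        rows = rng.choice(len(sub), size=want, replace=replace)
        phenos = random_phenotypes(want, rng)
        for ph, ridx in zip(phenos, rows):
            row = sub.iloc[int(ridx)]
            mass = float(row["mass"])
            tl_val, floor, r_final = assign_trophic(mass, taxon, trophic_table, rng)
            species.append(
                VirtualSpecies(
                    id=sid,
                    taxon=taxon,
                    body_mass=mass,
                    trophic_level=tl_val,
                    trophic_breadth_floor=floor,
                    basal=floor <= BASAL_RESOURCE_LEVEL,
                    phenotype=ph,
                    adaptive_capacity=float(rng.uniform(0.0, 1.0)),
                    niche_T=fit_axis(row["samples_T"], p_thresh),
                    niche_P=fit_axis(row["samples_P"], p_thresh),
                    match_threshold=r_final,
                )
            )
            sid += 1
    return pack_pool(species)


def pack_pool(species: list[VirtualSpecies]) -> SpeciesPool:
    n = len(species)
    counts = np.zeros((n, N_LETTERS), dtype=float)
    for i, sp in enumerate(species):
        counts[i] = phenotype_counts(sp.phenotype)
    return SpeciesPool(
        species=species,
        mass=np.array([sp.body_mass for sp in species], dtype=float),
        tl=np.array([sp.trophic_level for sp in species], dtype=float),
        floor=np.array([sp.trophic_breadth_floor for sp in species], dtype=float),
        basal=np.array([sp.basal for sp in species], dtype=bool),
        taxon_idx=np.array([TAXON_INDEX[sp.taxon] for sp in species], dtype=int),
        adaptive=np.array([sp.adaptive_capacity for sp in species], dtype=float),
        counts=counts,
        nT=params_array([sp.niche_T for sp in species]) if n else np.empty((0, 7)),
        nP=params_array([sp.niche_P for sp in species]) if n else np.empty((0, 7)),
    )
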