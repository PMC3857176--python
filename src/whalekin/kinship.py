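"""Maximum-likelihood pairwise relatedness from multilocus microsatellites.

Relatedness between two non-inbred individuals is parameterised by the IBD
coefficients k = (k0, k1, k2): the probabilities that the pair shares 0, 1
or 2 alleles identical by descent at a locus.  The coefficient of
relatedness is r = k2 + k1/2.  Common relationships sit at fixed points of
the simplex:

    unrelated        U  = (1, 0, 0)        r = 0
    half siblings    HS = (1/2, 1/2, 0)    r = 1/4
    full siblings    FS = (1/4, 1/2, 1/4)  r = 1/2
    parent-offspring PO = (0, 1, 0)        r = 1/2

The genotype-pair likelihood at one locus is k2*P2 + k1*P1 + k0*P0 where
P2, P1, P0 are the probabilities of observing the unordered genotype pair
given 2, 1 or 0 shared IBD alleles, computed from population allele
frequencies under Hardy-Weinberg (the standard seven-case table for
non-inbred pairs).  Multilocus log-likelihoods sum over loci typed in both
individuals; the unconstrained MLE of k is found by a deterministic coarse
grid search on the simplex followed by Nelder-Mead refinement.

Putative parent-offspring pairs must also be Mendelian-compatible (at least
one shared allele at every locus typed in both) and, for maternity, share
the mtDNA haplotype.  Because PO and FS both imply r >= 0.5, a detected PO
is tested against the FS alternative by simulating genotype pairs under FS
and locating the observed log-likelihood ratio in that distribution.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "NULL_ALLELE",
    "GenotypeRecord",
    "AlleleFrequencies",
    "KCoefficients",
    "RelatednessEstimate",
    "InsufficientDataError",
    "RELATIONSHIP_K",
    "RELATIONSHIP_ORDER",
    "load_genotypes",
    "write_genotypes",
    "read_genepop",
    "estimate_allele_frequencies",
    "genotype_pair_probs",
    "locus_pair_likelihood",
    "pair_loglikelihood",
    "mle_k",
    "classify_relationship",
    "po_compatibility",
    "test_po_vs_fs",
    "po_census",
    "simulate_genotype_pairs",
]

#: label reserved for the non-amplifying (null) allele
NULL_ALLELE = -1


class InsufficientDataError(ValueError):
    """Too few loci typed in both members of a pair."""


@dataclass(frozen=True)
class GenotypeRecord:
    """Multilocus genotype of one individual; allele pairs are unordered."""

    individual_id: str
    loci: tuple[tuple[int, int] | None, ...]
    mtdna_haplotype: str | None = None

    def __post_init__(self) -> None:
        canon = []
        for g in self.loci:
            if g is None:
                canon.append(None)
            else:
                a, b = g
                if a <= 0 or b <= 0:
                    raise ValueError(
                        f"{self.individual_id}: allele labels must be positive, got {g}"
                    )
                canon.append((a, b) if a <= b else (b, a))
        object.__setattr__(self, "loci", tuple(canon))

    @property
    def n_typed(self) -> int:
        return sum(g is not None for g in self.loci)


class AlleleFrequencies:
    """Per-locus allele frequency tables (optionally including a null allele)."""

    def __init__(self, per_locus: Sequence[Mapping[int, float]], tol: float = 1e-9):
        self.per_locus: list[dict[int, float]] = [dict(m) for m in per_locus]
        for i, m in enumerate(self.per_locus):
            if not m:
                raise ValueError(f"locus {i}: empty frequency table")
            total = sum(m.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"locus {i}: frequencies sum to {total}, not 1")
            if any(p <= 0 for p in m.values()):
                raise ValueError(f"locus {i}: non-positive frequency")
        self._tol = tol

    @property
    def n_loci(self) -> int:
        return len(self.per_locus)

    def null_freq(self, locus: int) -> float:
        return self.per_locus[locus].get(NULL_ALLELE, 0.0)

    def arrays(self, locus: int) -> tuple[np.ndarray, np.ndarray]:
        """(allele labels, probabilities) for vectorised simulation."""
        labels = np.array(sorted(self.per_locus[locus]))
        probs = np.array([self.per_locus[locus][a] for a in labels])
        return labels, probs / probs.sum()

    @classmethod
    def equifrequent(cls, n_loci: int, n_alleles: int) -> "AlleleFrequencies":
        return cls([{a: 1.0 / n_alleles for a in range(1, n_alleles + 1)}] * n_loci)


@dataclass(frozen=True)
class KCoefficients:
    k0: float
    k1: float
    k2: float

    def __post_init__(self) -> None:
        for v in (self.k0, self.k1, self.k2):
            if not -1e-9 <= v <= 1 + 1e-9:
                raise ValueError(f"k coefficient outside [0,1]: {self}")
        if abs(self.k0 + self.k1 + self.k2 - 1.0) > 1e-6:
            raise ValueError(f"k coefficients must sum to 1: {self}")

    @property
    def r(self) -> float:
        return self.k2 + self.k1 / 2.0

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.k0, self.k1, self.k2)


RELATIONSHIP_K: dict[str, KCoefficients] = {
    "U": KCoefficients(1.0, 0.0, 0.0),
    "HS": KCoefficients(0.5, 0.5, 0.0),
    "FS": KCoefficients(0.25, 0.5, 0.25),
    "PO": KCoefficients(0.0, 1.0, 0.0),
}

#: tie-break preference, least related first (conservative against kin claims)
RELATIONSHIP_ORDER = ("U", "HS", "FS", "PO")


@dataclass
class RelatednessEstimate:
    id_a: str
    id_b: str
    n_loci: int
    k_hat: KCoefficients
    r_hat: float
    lnl: dict[str, float]  # per hypothesis plus "unconstrained"
    best_relationship: str
    po_vs_fs_p: float | None = None


# ---------------------------------------------------------------------------
# Genotype I/O


def load_genotypes(path) -> list[GenotypeRecord]:
    """Read the genotype CSV: individual_id, mtdna_haplotype, locus*_a/_b; 0 = missing."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "individual_id" not in df.columns:
        raise ValueError("genotype CSV needs an individual_id column")
    locus_names = [c[:-2] for c in df.columns if c.endswith("_a") and f"{c[:-2]}_b" in df.columns]
    if not locus_names:
        raise ValueError("no locus columns (expected pairs like locus1_a, locus1_b)")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        loci: list[tuple[int, int] | None] = []
        for name in locus_names:
            a, b = int(d[f"{name}_a"] or 0), int(d[f"{name}_b"] or 0)
            loci.append(None if a == 0 or b == 0 else (a, b))
        hap = str(d.get("mtdna_haplotype", "")).strip() or None
        records.append(GenotypeRecord(str(d["individual_id"]), tuple(loci), hap))
    return records


def write_genotypes(records: Sequence[GenotypeRecord], path) -> pd.DataFrame:
    n_loci = records[0].loci.__len__() if records else 0
    rows = []
    for rec in records:
        row = {"individual_id": rec.individual_id, "mtdna_haplotype": rec.mtdna_haplotype or ""}
        for i, g in enumerate(rec.loci, start=1):
            row[f"locus{i}_a"], row[f"locus{i}_b"] = (0, 0) if g is None else g
        rows.append(row)
    cols = ["individual_id", "mtdna_haplotype"] + [
        f"locus{i}_{s}" for i in range(1, n_loci + 1) for s in ("a", "b")
    ]
    df = pd.DataFrame(rows, columns=cols)
    if path is not None:
        df.to_csv(path, index=False)
    return df


def read_genepop(path) -> list[GenotypeRecord]:
    """Minimal GenePop reader (2- or 3-digit alleles, one individual per line)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise ValueError("empty GenePop file")
    body = lines[1:]  # first line is a title
    locus_names: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        locus_names.extend(s.strip() for s in body[i].split(",") if s.strip())
        i += 1
    records = []
    for ln in body[i:]:
        s = ln.strip()
        if not s or s.lower() == "pop":
            continue
        name, _, geno = s.partition(",")
        fields = geno.split()
        if len(fields) != len(locus_names):
            raise ValueError(f"individual {name.strip()!r}: expected {len(locus_names)} loci")
        width = len(fields[0]) // 2
        loci = []
        for f in fields:
            a, b = int(f[:width]), int(f[width:])
            loci.append(None if a == 0 or b == 0 else (a, b))
        records.append(GenotypeRecord(name.strip(), tuple(loci)))
    return records


# ---------------------------------------------------------------------------
# Allele frequencies


def estimate_allele_frequencies(
    genotypes: Iterable[GenotypeRecord], null_alleles: bool = False
) -> AlleleFrequencies:
    """Allele counting over the whole panel (focal pairs included).

    With ``null_alleles`` on, a per-locus null frequency is estimated from
    homozygote excess (Brookfield 1996 estimator 1, r = (He-Ho)/(1+He));
    observed frequencies are rescaled by (1-r) and the null is appended as
    an extra allele.
    """
    recs = list(genotypes)
    if not recs:
        raise ValueError("no genotypes")
    n_loci = len(recs[0].loci)
    per_locus: list[dict[int, float]] = []
    for l in range(n_loci):
        counts: dict[int, int] = {}
        n_typed = 0
        n_hom = 0
        for rec in recs:
            g = rec.loci[l]
            if g is None:
                continue
            n_typed += 1
            n_hom += g[0] == g[1]
            for a in g:
                counts[a] = counts.get(a, 0) + 1
        if n_typed == 0:
            raise ValueError(f"locus {l}: no typed individuals")
        total = sum(counts.values())
        freqs = {a: c / total for a, c in counts.items()}
        if null_alleles:
            he = 1.0 - sum(p * p for p in freqs.values())
            ho = 1.0 - n_hom / n_typed
            r_null = max(0.0, (he - ho) / (1.0 + he))
            if r_null > 0:
                freqs = {a: p * (1.0 - r_null) for a, p in freqs.items()}
                freqs[NULL_ALLELE] = r_null
        per_locus.append(freqs)
    return AlleleFrequencies(per_locus)


# ---------------------------------------------------------------------------
# Genotype-pair likelihood


def genotype_pair_probs(
    g1: tuple[int, int], g2: tuple[int, int], locus_freqs: Mapping[int, float]
) -> tuple[float, float, float]:
    """(P0, P1, P2): unordered genotype-pair probabilities given 0/1/2 IBD alleles.

    Equivalent to the seven-case table for non-inbred pairs; e.g. for
    g1 = AiAi, g2 = AiAj it yields P2 = 0, P1 = pi^2 pj, P0 = 2 pi^3 pj.
    """
    a, b = g1
    c, d = g2
    try:
        pa, pb, pc, pd_ = locus_freqs[a], locus_freqs[b], locus_freqs[c], locus_freqs[d]
    except KeyError as exc:
        raise ValueError(f"allele {exc.args[0]} absent from frequency table") from None
    hw1 = pa * pb * (2.0 if a != b else 1.0)
    hw2 = pc * pd_ * (2.0 if c != d else 1.0)
    p0 = hw1 * hw2
    p2 = hw1 if tuple(sorted(g1)) == tuple(sorted(g2)) else 0.0
    terms = (a == c) * pd_ + (a == d) * pc + (b == c) * pd_ + (b == d) * pc
    p1 = hw1 * (0.25 if c == d else 0.5) * terms
    return p0, p1, p2


def locus_pair_likelihood(
    g1: tuple[int, int],
    g2: tuple[int, int],
    locus_freqs: Mapping[int, float],
    k: KCoefficients | tuple[float, float, float],
) -> float:
    """Likelihood of one observed genotype pair at one locus given k."""
    k0, k1, k2 = k.as_tuple() if isinstance(k, KCoefficients) else k
    p0, p1, p2 = genotype_pair_probs(g1, g2, locus_freqs)
    return k0 * p0 + k1 * p1 + k2 * p2


def _genotype_options(g: tuple[int, int], null_freq_present: bool) -> list[tuple[int, int]]:
    # an observed homozygote may truly be a null heterozygote
    if null_freq_present and g[0] == g[1]:
        return [g, (NULL_ALLELE, g[0])]
    return [g]


def _case_table(
    rec1: GenotypeRecord,
    rec2: GenotypeRecord,
    freqs: AlleleFrequencies,
    min_loci: int = 6,
) -> np.ndarray:
    """Per-shared-locus (P0, P1, P2) rows; null-allele ambiguity summed out."""
    rows = []
    for l, (g1, g2) in enumerate(zip(rec1.loci, rec2.loci)):
        if g1 is None or g2 is None:
            continue
        table = freqs.per_locus[l]
        has_null = NULL_ALLELE in table
        p0 = p1 = p2 = 0.0
        for h1 in _genotype_options(g1, has_null):
            for h2 in _genotype_options(g2, has_null):
                q0, q1, q2 = genotype_pair_probs(h1, h2, table)
                p0 += q0
                p1 += q1
                p2 += q2
        rows.append((p0, p1, p2))
    if len(rows) < min_loci:
        raise InsufficientDataError(
            f"pair ({rec1.individual_id}, {rec2.individual_id}): "
            f"{len(rows)} shared loci < min_loci={min_loci}"
        )
    return np.asarray(rows)


def _lnl_at(table: np.ndarray, k: tuple[float, float, float]) -> float:
    mix = table @ np.asarray(k)
    if np.any(mix <= 0):
        return -np.inf
    return float(np.log(mix).sum())


def pair_loglikelihood(
    pair: tuple[GenotypeRecord, GenotypeRecord],
    freqs: AlleleFrequencies,
    k: KCoefficients | tuple[float, float, float],
    min_loci: int = 6,
) -> float:
    """Multilocus log-likelihood over loci typed in both pair members."""
    kt = k.as_tuple() if isinstance(k, KCoefficients) else tuple(k)
    return _lnl_at(_case_table(pair[0], pair[1], freqs, min_loci), kt)


# ---------------------------------------------------------------------------
# Maximisation over the k simplex


def _simplex_grid(step: float = 0.05) -> np.ndarray:
    pts = []
    n = round(1 / step)
    for i in range(n + 1):
        for j in range(n + 1 - i):
            k0, k2 = i * step, j * step
            pts.append((k0, 1.0 - k0 - k2, k2))
    return np.asarray(pts)


_GRID = _simplex_grid(0.05)


def _mle_from_table(table: np.ndarray) -> tuple[KCoefficients, float]:
    # coarse grid (deterministic) ...
    with np.errstate(divide="ignore"):
        mix = table @ _GRID.T  # (loci, grid)
        lnls = np.where(mix > 0, np.log(np.maximum(mix, 1e-300)), -np.inf).sum(axis=0)
    order = np.argsort(lnls)[::-1]
    best = int(order[0])
    best_lnl = float(lnls[best])

    # ... then local refinement in (k0, k2) from the top grid points
    def negll(z: np.ndarray) -> float:
        k0, k2 = z
        k1 = 1.0 - k0 - k2
        viol = max(0.0, -k0) + max(0.0, -k2) + max(0.0, -k1)
        if viol > 0:
            return 1e18 * (1.0 + viol)
        mix = table @ np.array([k0, k1, k2])
        if np.any(mix <= 0):
            return 1e18
        return -float(np.log(mix).sum())

    best_k = (_GRID[best, 0], _GRID[best, 1], _GRID[best, 2])
    for start in order[:3]:
        if not np.isfinite(lnls[start]):
            continue
        res = minimize(
            negll,
            np.array([_GRID[start, 0], _GRID[start, 2]]),
            method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 600},
        )
        if np.isfinite(res.fun) and -res.fun > best_lnl:
            k0, k2 = np.clip(res.x, 0.0, 1.0)
            if k0 + k2 > 1.0:  # project tiny constraint violations back
                excess = k0 + k2 - 1.0
                k0, k2 = k0 - excess / 2, k2 - excess / 2
            best_k = (k0, 1.0 - k0 - k2, k2)
            best_lnl = -float(res.fun)
    return KCoefficients(*best_k), best_lnl


def mle_k(
    pair: tuple[GenotypeRecord, GenotypeRecord],
    freqs: AlleleFrequencies,
    min_loci: int = 6,
) -> tuple[KCoefficients, float]:
    """Unconstrained MLE of (k0, k1, k2) on the simplex, with its lnL.

    Deterministic: 0.05-step grid initialisation plus Nelder-Mead
    refinement to tolerance 1e-8; no stochastic restarts.
    """
    return _mle_from_table(_case_table(pair[0], pair[1], freqs, min_loci))


def classify_relationship(
    pair: tuple[GenotypeRecord, GenotypeRecord],
    freqs: AlleleFrequencies,
    min_loci: int = 6,
) -> RelatednessEstimate:
    """Most likely of U / HS / FS / PO, with the unconstrained MLE attached.

    Ties are broken toward the less related hypothesis (U > HS > FS > PO).
    """
    rec1, rec2 = pair
    table = _case_table(rec1, rec2, freqs, min_loci)
    lnl = {name: _lnl_at(table, k.as_tuple()) for name, k in RELATIONSHIP_K.items()}
    k_hat, lnl_hat = _mle_from_table(table)
    lnl["unconstrained"] = lnl_hat
    best = "U"
    for name in RELATIONSHIP_ORDER:
        if lnl[name] > lnl[best]:
            best = name
    return RelatednessEstimate(
        id_a=rec1.individual_id,
        id_b=rec2.individual_id,
        n_loci=table.shape[0],
        k_hat=k_hat,
        r_hat=k_hat.r,
        lnl=lnl,
        best_relationship=best,
    )


# ---------------------------------------------------------------------------
# Parent-offspring screening


def po_compatibility(
    pair: tuple[GenotypeRecord, GenotypeRecord], maternal: bool = True
) -> bool:
    """Mendelian/mtDNA screen for a putative parent-offspring pair.

    True iff the pair shares at least one allele at every locus typed in
    both and, when ``maternal`` and both haplotypes are known, the mtDNA
    haplotypes match (drop ``maternal`` for putative father-offspring).
    """
    rec1, rec2 = pair
    for g1, g2 in zip(rec1.loci, rec2.loci):
        if g1 is None or g2 is None:
            continue
        if not set(g1) & set(g2):
            return False
    if maternal and rec1.mtdna_haplotype and rec2.mtdna_haplotype:
        if rec1.mtdna_haplotype != rec2.mtdna_haplotype:
            return False
    return True


def _mtdna_match(rec1: GenotypeRecord, rec2: GenotypeRecord) -> bool | None:
    if rec1.mtdna_haplotype and rec2.mtdna_haplotype:
        return rec1.mtdna_haplotype == rec2.mtdna_haplotype
    return None


# ---------------------------------------------------------------------------
# Simulation and the PO-vs-FS test


def _draw_pairs_for_locus(
    labels: np.ndarray, probs: np.ndarray, k: tuple[float, float, float], n: int, rng
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Simulate n unordered genotype pairs at one locus under IBD mix k.

    Returns index arrays (a, b, c, d) into ``labels``.
    """
    a = rng.choice(len(probs), size=n, p=probs)
    b = rng.choice(len(probs), size=n, p=probs)
    mode = rng.choice(3, size=n, p=[k[0], k[1], k[2]])
    w1 = rng.choice(len(probs), size=n, p=probs)
    w2 = rng.choice(len(probs), size=n, p=probs)
    shared = np.where(rng.integers(0, 2, size=n) == 0, a, b)
    c = np.where(mode == 2, a, np.where(mode == 1, shared, w1))
    d = np.where(mode == 2, b, w2)
    return a, b, c, d


def _case_probs_vec(a, b, c, d, p) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pa, pb, pc, pd_ = p[a], p[b], p[c], p[d]
    hw1 = np.where(a == b, pa * pa, 2 * pa * pb)
    hw2 = np.where(c == d, pc * pc, 2 * pc * pd_)
    p0 = hw1 * hw2
    same = (np.minimum(a, b) == np.minimum(c, d)) & (np.maximum(a, b) == np.maximum(c, d))
    p2 = np.where(same, hw1, 0.0)
    terms = (a == c) * pd_ + (a == d) * pc + (b == c) * pd_ + (b == d) * pc
    p1 = hw1 * np.where(c == d, 0.25, 0.5) * terms
    return p0, p1, p2


def simulate_genotype_pairs(
    freqs: AlleleFrequencies,
    k: KCoefficients | tuple[float, float, float],
    n_pairs: int,
    rng: np.random.Generator,
    loci: Sequence[int] | None = None,
) -> list[tuple[GenotypeRecord, GenotypeRecord]]:
    """Draw genotype pairs with per-locus IBD state sampled from k."""
    kt = k.as_tuple() if isinstance(k, KCoefficients) else tuple(k)
    loci = range(freqs.n_loci) if loci is None else loci
    genos1 = [[] for _ in range(n_pairs)]
    genos2 = [[] for _ in range(n_pairs)]
    for l in loci:
        labels, probs = freqs.arrays(l)
        a, b, c, d = _draw_pairs_for_locus(labels, probs, kt, n_pairs, rng)
        for i in range(n_pairs):
            genos1[i].append((int(labels[a[i]]), int(labels[b[i]])))
            genos2[i].append((int(labels[c[i]]), int(labels[d[i]])))
    return [
        (
            GenotypeRecord(f"sim{i}_a", tuple(genos1[i])),
            GenotypeRecord(f"sim{i}_b", tuple(genos2[i])),
        )
        for i in range(n_pairs)
    ]


def _simulate_fs_lambda(
    freqs: AlleleFrequencies, loci: Sequence[int], n_sim: int, rng
) -> np.ndarray:
    """Vectorised draw of Lambda = lnL(PO) - lnL(FS) for pairs simulated under FS."""
    lnl_po = np.zeros(n_sim)
    lnl_fs = np.zeros(n_sim)
    fs = RELATIONSHIP_K["FS"].as_tuple()
    for l in loci:
        _, probs = freqs.arrays(l)
        a, b, c, d = _draw_pairs_for_locus(None, probs, fs, n_sim, rng)
        p0, p1, p2 = _case_probs_vec(a, b, c, d, probs)
        with np.errstate(divide="ignore"):
            lnl_po += np.where(p1 > 0, np.log(np.maximum(p1, 1e-300)), -np.inf)
            lnl_fs += np.log(fs[0] * p0 + fs[1] * p1 + fs[2] * p2)
    return lnl_po - lnl_fs


def test_po_vs_fs(
    pair: tuple[GenotypeRecord, GenotypeRecord],
    freqs: AlleleFrequencies,
    n_sim: int = 10**6,
    seed: int | np.random.Generator | None = None,
    min_loci: int = 6,
) -> float:
    """p-value for PO (null) against the FS alternative by simulation.

    The statistic is Lambda = lnL(PO) - lnL(FS) for the observed pair;
    ``n_sim`` genotype pairs are simulated under FS at the pair's typed
    loci and p is the fraction with simulated Lambda >= the observed one.
    Small p means the observed pair looks more PO-like than full siblings
    typically do, rejecting FS.
    """
    if n_sim < 100:
        raise ValueError(f"n_sim={n_sim} too small to be informative (need >= 100)")
    rec1, rec2 = pair
    table = _case_table(rec1, rec2, freqs, min_loci)
    lam_obs = _lnl_at(table, RELATIONSHIP_K["PO"].as_tuple()) - _lnl_at(
        table, RELATIONSHIP_K["FS"].as_tuple()
    )
    loci = [
        l for l, (g1, g2) in enumerate(zip(rec1.loci, rec2.loci)) if g1 is not None and g2 is not None
    ]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam_sim = _simulate_fs_lambda(freqs, loci, n_sim, rng)
    return float(np.mean(lam_sim >= lam_obs))


# ---------------------------------------------------------------------------
# Census


def po_census(
    genotypes: Sequence[GenotypeRecord],
    freqs: AlleleFrequencies | None = None,
    classes: Mapping[str, str] | None = None,
    min_loci: int = 6,
    n_sim: int = 0,
    seed: int | None = None,
    maternal: bool = True,
) -> pd.DataFrame:
    """Scan all unordered pairs; report those classified PO and PO-compatible.

    ``classes`` optionally maps individual ids to a sighting class
    (resighted / non_resighted / stranded) carried into the output.  With
    ``n_sim`` > 0 each detected PO pair also gets a PO-vs-FS p-value.
    """
    if len(genotypes) < 2:
        raise ValueError("need at least 2 genotyped individuals")
    if freqs is None:
        freqs = estimate_allele_frequencies(genotypes)
    rng = np.random.default_rng(seed)
    rows = []
    for rec1, rec2 in itertools.combinations(genotypes, 2):
        if not po_compatibility((rec1, rec2), maternal=maternal):
            continue
        try:
            est = classify_relationship((rec1, rec2), freqs, min_loci)
        except InsufficientDataError:
            continue
        if est.best_relationship != "PO":
            continue
        p = None
        if n_sim:
            p = test_po_vs_fs((rec1, rec2), freqs, n_sim=n_sim, seed=rng, min_loci=min_loci)
        rows.append(
            {
                "id1": est.id_a,
                "id2": est.id_b,
                "n_loci": est.n_loci,
                "k0": est.k_hat.k0,
                "k1": est.k_hat.k1,
                "k2": est.k_hat.k2,
                "r_hat": est.r_hat,
                "lnl_U": est.lnl["U"],
                "lnl_HS": est.lnl["HS"],
                "lnl_FS": est.lnl["FS"],
                "lnl_PO": est.lnl["PO"],
                "best": est.best_relationship,
                "po_compatible": True,
                "mtdna_match": _mtdna_match(rec1, rec2),
                "p_po_vs_fs": p,
                "class_1": (classes or {}).get(rec1.individual_id),
                "class_2": (classes or {}).get(rec2.individual_id),
            }
        )
    cols = [
        "id1", "id2", "n_loci", "k0", "k1", "k2", "r_hat",
        "lnl_U", "lnl_HS", "lnl_FS", "lnl_PO", "best",
        "po_compatible", "mtdna_match", "p_po_vs_fs", "class_1", "class_2",
    ]
    return pd.DataFrame(rows, columns=cols)
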