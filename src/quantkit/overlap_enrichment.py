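"""Monte-Carlo gene-set overlap enrichment with empirical p-values.

The question: does a candidate gene set (e.g. disease candidate genes)
contain more genes carrying an annotation (e.g. apoptotic process,
GO:0006915) than random same-size draws from the gene universe?  The answer
is empirical: draw ``n_sim`` random sets of the same size without
replacement, record the annotated count of each, and report the upper-tail
proportion of simulated counts at or beyond the observed overlap.  When no
simulated count reaches the observation the estimate is reported as the
bound ``p < 1/n_sim`` rather than a literal zero.

An exact Fisher test on 2x2 tables is provided for the companion
contingency-style comparisons, built on the same hypergeometric model the
simulation converges to.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from ._util import rng_from

__all__ = [
    "AnnotatedUniverse",
    "OverlapNull",
    "EmpiricalP",
    "normalize_symbol",
    "observed_overlap",
    "simulate_overlap_null",
    "empirical_p",
    "fisher_exact_overlap",
    "annotation_sharing_fraction",
    "read_universe_tsv",
    "read_gene_set",
]

SUMMARY_PERCENTILES = (5.0, 25.0, 50.0, 75.0, 95.0, 99.0)
# chunk cap for the vectorized without-replacement sampler (floats held at once)
_VECTOR_BUDGET = 20_000_000


def normalize_symbol(symbol: str) -> str:
    """Canonical gene-symbol form: uppercase, stripped; no alias resolution."""
    return str(symbol).strip().upper()


@dataclass(frozen=True)
class AnnotatedUniverse:
    """A gene universe with one boolean annotation per gene."""

    genes: tuple[str, ...]
    annotated: np.ndarray  # bool, parallel to genes

    def __post_init__(self) -> None:
        genes = tuple(normalize_symbol(g) for g in self.genes)
        flags = np.asarray(self.annotated, dtype=bool)
        if len(genes) != flags.size:
            raise ValueError("genes and annotation flags differ in length")
        if len(set(genes)) != len(genes):
            raise ValueError("gene symbols must be unique")
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "annotated", flags)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_annotated(self) -> int:
        return int(self.annotated.sum())

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AnnotatedUniverse":
        return cls(
            genes=tuple(df["gene"].astype(str)),
            annotated=df["annotated"].to_numpy().astype(bool),
        )


@dataclass(frozen=True)
class OverlapNull:
    """Monte-Carlo distribution of annotated counts in random same-size sets."""

    counts: np.ndarray  # int, length n_sim
    k: int  # candidate-set size drawn per simulation
    n_sim: int
    seed: int

    def summary(self) -> dict:
        c = self.counts
        out = {
            "min": int(c.min()),
            "mean": float(c.mean()),
            "max": int(c.max()),
        }
        for q in SUMMARY_PERCENTILES:
            out[f"p{q:g}"] = float(np.percentile(c, q))
        return out


@dataclass(frozen=True)
class EmpiricalP:
    observed: int
    estimate: float  # #{sim >= observed} / n_sim
    n_sim: int
    is_lower_bound: bool  # True when no simulated count reached the observation

    @property
    def reported(self) -> str:
        if self.is_lower_bound:
            return f"p < {1.0 / self.n_sim:.2e}"
        return f"p = {self.estimate:.4g}"


def observed_overlap(candidate: Sequence[str], universe: AnnotatedUniverse):
    """Annotated candidate genes present in the universe.

    Returns ``(count, missing)``: the number of candidate genes present and
    flagged annotated, and the tuple of candidate symbols absent from the
    universe (reported separately, never silently dropped).
    """
    cand = list(dict.fromkeys(normalize_symbol(g) for g in candidate))
    if not cand:
        raise ValueError("candidate set is empty")
    flag = dict(zip(universe.genes, universe.annotated))
    missing = tuple(g for g in cand if g not in flag)
    count = sum(bool(flag[g]) for g in cand if g in flag)
    return count, missing


def _sample_counts(flags: np.ndarray, k: int, n_sim: int, rng) -> np.ndarray:
    """Annotated counts of n_sim uniform without-replacement draws of size k.

    Each simulation ranks N iid uniform keys and takes the k smallest -- an
    exact uniform draw without replacement -- vectorized in chunks to bound
    memory.
    """
    n = flags.size
    counts = np.empty(n_sim, dtype=np.int64)
    chunk = max(1, _VECTOR_BUDGET // n)
    done = 0
    while done < n_sim:
        m = min(chunk, n_sim - done)
        keys = rng.random((m, n))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        counts[done : done + m] = flags[idx].sum(axis=1)
        done += m
    return counts


def simulate_overlap_null(
    universe: AnnotatedUniverse, k: int, n_sim: int = 100_000, seed: int = 0
) -> OverlapNull:
    """Monte-Carlo null of annotated counts among random k-gene sets.

    Each simulation draws k genes uniformly without replacement from the
    universe and records how many are annotated; reproducible under seed.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > universe.n_genes:
        raise ValueError("k exceeds the universe size")
    rng = rng_from(seed)
    counts = _sample_counts(universe.annotated, k, int(n_sim), rng)
    return OverlapNull(counts=counts, k=k, n_sim=int(n_sim), seed=seed)


def empirical_p(null: OverlapNull, observed: int) -> EmpiricalP:
    """Upper-tail empirical p: #{simulated count >= observed} / n_sim.

    Inclusive at the observation; a zero tail is reported as the lower bound
    ``p < 1/n_sim`` instead of a literal zero.
    """
    if observed < 0:
        raise ValueError("observed overlap cannot be negative")
    if null.counts.size == 0:
        raise ValueError("empty null distribution")
    exceed = int((null.counts >= observed).sum())
    return EmpiricalP(
        observed=int(observed),
        estimate=exceed / null.n_sim,
        n_sim=null.n_sim,
        is_lower_bound=(exceed == 0),
    )


def fisher_exact_overlap(a: int, b: int, c: int, d: int):
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Exact conditional test: with margins fixed, the top-left cell is
    hypergeometric; the two-sided p sums the probabilities of all tables at
    most as likely as the observed one.  Returns ``(odds_ratio, p)`` with
    odds ratio (a*d)/(b*c) under the 0/inf conventions for zero cells.
    """
    for v in (a, b, c, d):
        if int(v) != v or v < 0:
            raise ValueError("table entries must be nonnegative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        raise ValueError("table total must be positive")

    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)

    row1, col1 = a + b, a + c
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = hypergeom.pmf(support, n, row1, col1)
    p_obs = hypergeom.pmf(a, n, row1, col1)
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-9)].sum())
    return odds, min(p, 1.0)


def annotation_sharing_fraction(shared_flags) -> float:
    """Fraction of annotation terms shared across species.

    Given one boolean per human-gene annotation term indicating whether the
    fly homolog carries the same term, returns shared / total.
    """
    flags = np.asarray(shared_flags, dtype=bool)
    if flags.size == 0:
        raise ValueError("no annotation terms supplied")
    return float(flags.sum() / flags.size)


def read_universe_tsv(path) -> AnnotatedUniverse:
    df = pd.read_csv(path, sep="\t")
    df["annotated"] = df["annotated"].astype(int).astype(bool)
    return AnnotatedUniverse.from_frame(df)


def read_gene_set(path) -> list[str]:
    """One-symbol-per-line text, or single-row GMT (name, description, genes...)."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) == 1 and "\t" in lines[0]:
        fields = lines[0].split("\t")
        if len(fields) > 2:
            return [normalize_symbol(g) for g in fields[2:]]
    return [normalize_symbol(ln.split("\t")[0]) for ln in lines]
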