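"""Namespace-generic over-representation analysis.

Works for any protein→term annotation table — GO-like (with an optional
acyclic term→parent relation and true-path propagation), pathway-like or
disease-like.  The test is the one-sided hypergeometric upper tail: for a
study set of n annotated proteins drawn from a background of N, a term
annotating K background proteins and k study proteins scores

    p = P[X >= k],  X ~ Hypergeometric(N, K, n),

followed by Benjamini–Hochberg step-up adjustment across all tested terms.
A term is called significant when p_adj < alpha AND at least ``min_drivers``
study proteins carry it — terms driven by two or fewer proteins are flagged
but never called, since such calls are dominated by annotation noise.
Terms with k = 0 cannot be over-represented and are excluded from the BH
family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import (
    BackgroundMismatchError,
    CyclicOntologyError,
    EmptyInputError,
    InvalidCountsError,
    InvalidPValueError,
)

#: preset significance profiles
PROFILES = {"bingo": 0.05, "webgestalt": 0.01}


@dataclass
class AnnotationMap:
    """protein → term-set annotations, with an optional is-a parent relation."""

    protein_to_terms: dict[str, set[str]]
    term_parents: dict[str, set[str]] = field(default_factory=dict)
    namespace: str = "generic"

    def proteins(self) -> set[str]:
        return set(self.protein_to_terms)

    def terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.protein_to_terms.values():
            out |= ts
        return out


@dataclass
class EnrichmentResult:
    """One tested term with its contingency counts and verdict."""

    term: str
    k: int  # annotated proteins in the study set
    K: int  # annotated proteins in the background
    n: int  # study-set size counted against the background
    N: int  # background size
    p_raw: float
    p_adj: float
    significant: bool

    @property
    def frequency(self) -> float:
        """Fraction of the study set carrying the term."""
        return self.k / self.n if self.n else 0.0


def _ancestors(term: str, parents: Mapping[str, set[str]], cache: dict[str, set[str]],
               stack: set[str]) -> set[str]:
    if term in cache:
        return cache[term]
    if term in stack:
        raise CyclicOntologyError(f"cycle through term {term!r}")
    stack.add(term)
    anc: set[str] = set()
    for p in parents.get(term, ()):
        anc.add(p)
        anc |= _ancestors(p, parents, cache, stack)
    stack.discard(term)
    if term in anc:
        raise CyclicOntologyError(f"term {term!r} is its own ancestor")
    cache[term] = anc
    return anc


def propagate_annotations(annotation_map: AnnotationMap) -> AnnotationMap:
    """Apply the true-path rule: annotate every protein to all ancestors.

    Returns a new map; raises :class:`CyclicOntologyError` on a cyclic
    parent relation.
    """
    cache: dict[str, set[str]] = {}
    # touch every term so cycles are detected even without annotations
    for term in set(annotation_map.term_parents):
        _ancestors(term, annotation_map.term_parents, cache, set())
    closed: dict[str, set[str]] = {}
    for protein, terms in annotation_map.protein_to_terms.items():
        full = set(terms)
        for t in terms:
            full |= _ancestors(t, annotation_map.term_parents, cache, set())
        closed[protein] = full
    return AnnotationMap(
        protein_to_terms=closed,
        term_parents=dict(annotation_map.term_parents),
        namespace=annotation_map.namespace,
    )


def hypergeometric_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise InvalidCountsError(f"invalid counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    Sort ascending, multiply p_(i) by m/i, enforce monotonicity from the
    largest rank down, cap at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InvalidPValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return [float(x) for x in out]


def enrich(
    study_set: Iterable[str],
    annotation_map: AnnotationMap,
    background: Iterable[str] | None = None,
    alpha: float = 0.05,
    min_drivers: int = 3,
) -> list[EnrichmentResult]:
    """Over-representation of every term with >= 1 study annotation.

    ``background`` defaults to all annotated proteins in the map (the
    network-as-reference convention); pass an explicit collection for a
    whole-annotation background.  Study proteins without annotations still
    count toward n via their membership in the background.  Results are
    sorted by adjusted p-value, then term.
    """
    study = sorted(set(study_set))
    if not study:
        raise EmptyInputError("study set is empty")
    bg = set(background) if background is not None else annotation_map.proteins()
    missing = [p for p in study if p not in bg]
    if missing:
        raise BackgroundMismatchError(f"study proteins absent from background: {missing[:5]}")
    ann = annotation_map.protein_to_terms
    N = len(bg)
    n = len(study)
    term_K: dict[str, int] = {}
    term_k: dict[str, int] = {}
    for protein in bg:
        for term in ann.get(protein, ()):
            term_K[term] = term_K.get(term, 0) + 1
    for protein in study:
        for term in ann.get(protein, ()):
            term_k[term] = term_k.get(term, 0) + 1
    tested = sorted(term_k)  # k >= 1 by construction
    p_raw = [hypergeometric_upper_tail(term_k[t], term_K[t], n, N) for t in tested]
    p_adj = bh_adjust(p_raw)
    results = [
        EnrichmentResult(
            term=t,
            k=term_k[t],
            K=term_K[t],
            n=n,
            N=N,
            p_raw=pr,
            p_adj=pa,
            significant=bool(pa < alpha and term_k[t] >= min_drivers),
        )
        for t, pr, pa in zip(tested, p_raw, p_adj)
    ]
    results.sort(key=lambda r: (r.p_adj, r.term))
    return results


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """TSV-ready table (term, k, K, frequency, p_raw, p_adj, significant)."""
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "frequency": r.frequency,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "significant": r.significant,
            }
            for r in results
        ]
    )


def read_annotations(
    annotation_path: str | Path,
    parent_path: str | Path | None = None,
    namespace: str = "generic",
) -> AnnotationMap:
    """Read a 2-column (accession, term) TSV, optionally with a (term, parent) TSV."""
    p2t: dict[str, set[str]] = {}
    for line in Path(annotation_path).read_text(encoding="utf-8").splitlines():
        if not line or line.startswith("#") or line.startswith("accession\t"):
            continue
        acc, term = line.split("\t")[:2]
        p2t.setdefault(acc, set()).add(term)
    parents: dict[str, set[str]] = {}
    if parent_path is not None:
        for line in Path(parent_path).read_text(encoding="utf-8").splitlines():
            if not line or line.startswith("#") or line.startswith("term\t"):
                continue
            term, parent = line.split("\t")[:2]
            parents.setdefault(term, set()).add(parent)
    return AnnotationMap(protein_to_terms=p2t, term_parents=parents, namespace=namespace)


def annotations_from_frame(table: pd.DataFrame, namespace: str = "generic") -> AnnotationMap:
    """Build an AnnotationMap from a two-column (accession, term) DataFrame."""
    p2t: dict[str, set[str]] = {}
    for acc, term in zip(table.iloc[:, 0], table.iloc[:, 1]):
        p2t.setdefault(str(acc), set()).add(str(term))
    return AnnotationMap(protein_to_terms=p2t, namespace=namespace)
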