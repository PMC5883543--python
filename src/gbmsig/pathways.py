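"""Over-representation filtering of the candidate feature pool.

Candidate genes for feature selection are restricted to members of enriched,
resistance-relevant gene sets. Enrichment is the exact upper-tail
hypergeometric test against a stated background, with Benjamini-Hochberg
correction across sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class EnrichmentRow:
    set_name: str
    set_size: int
    overlap: int
    p_value: float
    q_value: float


def enrich(
    query: Sequence[str],
    sets: dict[str, list[str]],
    background: Sequence[str],
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of the query in each gene set.

    Each set is intersected with the background before testing;
    p = P(X >= overlap) with X ~ hypergeometric(|background|,
    |set ∩ background|, |query|). Rows come back sorted by p (ties by name),
    with BH q-values computed across all tested sets.
    """
    bg = set(background)
    q = set(query)
    if not bg or not q:
        raise ValueError("query and background must be non-empty")
    if not q <= bg:
        raise ValueError("query must be a subset of the background")

    rows = []
    for name, members in sets.items():
        in_bg = set(members) & bg
        overlap = len(in_bg & q)
        p = float(hypergeom.sf(overlap - 1, len(bg), len(in_bg), len(q)))
        rows.append((name, len(in_bg), overlap, min(p, 1.0)))
    _, q_values, _, _ = multipletests([r[3] for r in rows], method="fdr_bh")
    out = [
        EnrichmentRow(name, size, overlap, p, float(max(qv, p)))
        for (name, size, overlap, p), qv in zip(rows, q_values)
    ]
    return sorted(out, key=lambda r: (r.p_value, r.set_name))


def select_pathway_genes(
    rows: Iterable[EnrichmentRow],
    chosen_sets: Iterable[str],
    sets: dict[str, list[str]],
    query: Sequence[str],
) -> list[str]:
    """Union of members of the chosen sets, restricted to the query pool.

    The chosen names must have been tested (present in ``rows``); the output
    is deduplicated and sorted for determinism.
    """
    tested = {r.set_name for r in rows}
    chosen = list(chosen_sets)
    unknown = [name for name in chosen if name not in tested]
    if unknown:
        raise ValueError(f"chosen sets were not tested: {unknown}")
    pool: set[str] = set()
    for name in chosen:
        pool.update(sets[name])
    return sorted(pool & set(query))


def default_set_choice(
    rows: Iterable[EnrichmentRow],
    allowlist: Iterable[str] | None = None,
    q_cutoff: float = 0.05,
) -> list[str]:
    """Sets passing BH q <= cutoff, optionally intersected with an allowlist.

    The allowlist stands in for the curated choice of resistance-relevant
    pathway categories; without one, significance alone decides.
    """
    allowed = set(allowlist) if allowlist is not None else None
    return [
        r.set_name
        for r in rows
        if r.q_value <= q_cutoff and (allowed is None or r.set_name in allowed)
    ]
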