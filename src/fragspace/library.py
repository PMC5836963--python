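"""Library-level aggregation of per-compound fragment lists.

A fragment's frequency is the number of *compounds* containing it after
per-compound deduplication, not its raw occurrence count — two benzene
rings in one drug contribute one count.  This makes switching dummy-atom
cut points on a pure refinement: contexts that previously collapsed onto
one hydrogen-capped string separate into distinct capped patterns, so
the unique-fragment count can only grow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fragmenter import AssembledFragment

__all__ = ["FragmentLibrary", "CountSummary", "aggregate", "top_n", "count_distribution"]


@dataclass(frozen=True)
class FragmentLibrary:
    """Aggregate over compounds.

    freq
        canonical SMILES -> number of compounds containing the fragment.
    per_compound_counts
        compound_id -> unique-fragment count (zero allowed).
    n_fragmented
        number of compounds with at least one surviving fragment.
    """

    freq: dict[str, int]
    per_compound_counts: dict[str, int]
    n_fragmented: int

    @property
    def unique_fragments(self) -> int:
        return len(self.freq)


@dataclass(frozen=True)
class CountSummary:
    min: float
    q1: float
    median: float
    q3: float
    max: float


def aggregate(
    results: list[tuple[str, list[AssembledFragment | str]]]
) -> FragmentLibrary:
    """Build a FragmentLibrary from per-compound fragment lists.

    Each entry is ``(compound_id, fragments)`` where fragments are
    AssembledFragments or bare canonical SMILES, already deduplicated
    within the compound.  Duplicate compound ids are an error.
    """
    freq: dict[str, int] = {}
    per_compound: dict[str, int] = {}
    for compound_id, frags in results:
        if compound_id in per_compound:
            raise ValueError(f"duplicate compound_id {compound_id!r}")
        smiles = {f if isinstance(f, str) else f.capped_smiles for f in frags}
        per_compound[compound_id] = len(smiles)
        for s in smiles:
            freq[s] = freq.get(s, 0) + 1
    n_fragmented = sum(1 for c in per_compound.values() if c > 0)
    return FragmentLibrary(freq=freq, per_compound_counts=per_compound, n_fragmented=n_fragmented)


def top_n(lib: FragmentLibrary, n: int) -> list[tuple[str, int]]:
    """The n most frequent fragments, ties broken by SMILES ascending."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(lib.freq.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:n]


def count_distribution(lib: FragmentLibrary) -> CountSummary:
    """Five-number summary of per-compound fragment counts.

    Computed over fragmented compounds only (count >= 1); quartiles use
    linear interpolation between order statistics.
    """
    counts = np.array([c for c in lib.per_compound_counts.values() if c > 0], dtype=float)
    if counts.size == 0:
        raise ValueError("library has no fragmented compounds")
    q1, med, q3 = np.percentile(counts, [25, 50, 75], method="linear")
    return CountSummary(
        min=float(counts.min()), q1=float(q1), median=float(med), q3=float(q3),
        max=float(counts.max()),
    )
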