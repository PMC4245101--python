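"""Shared partition container for component- and community-side item groupings.

Both the forced-choice principal-component assignment and the network
community structure are represented as a :class:`Partition`: a mapping of
item labels to module identifiers, plus an explicit list of isolates (items
that lost all their edges under pruning and belong to no module).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping

import pandas as pd

__all__ = ["Partition"]


@dataclass(frozen=True)
class Partition:
    """Assignment of items to modules (clusters or components).

    Parameters
    ----------
    membership : mapping item -> module id
    isolates : items excluded from every module
    """

    membership: dict[str, Hashable]
    isolates: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        overlap = set(self.membership) & set(self.isolates)
        if overlap:
            raise ValueError(f"items both assigned and isolate: {sorted(overlap)}")

    @classmethod
    def from_membership(
        cls, membership: Mapping[str, Hashable], isolates: Iterable[str] = ()
    ) -> "Partition":
        return cls(dict(membership), frozenset(isolates))

    @classmethod
    def from_modules(
        cls, modules: Mapping[Hashable, Iterable[str]], isolates: Iterable[str] = ()
    ) -> "Partition":
        membership: dict[str, Hashable] = {}
        for mod, items in modules.items():
            for it in items:
                if it in membership:
                    raise ValueError(f"item {it!r} appears in more than one module")
                membership[it] = mod
        return cls(membership, frozenset(isolates))

    @property
    def items(self) -> frozenset[str]:
        return frozenset(self.membership)

    @property
    def modules(self) -> dict[Hashable, frozenset[str]]:
        out: dict[Hashable, set[str]] = {}
        for it, mod in self.membership.items():
            out.setdefault(mod, set()).add(it)
        return {m: frozenset(s) for m, s in out.items()}

    @property
    def n_modules(self) -> int:
        return len(set(self.membership.values()))

    def module_of(self, item: str) -> Hashable:
        return self.membership[item]

    def restrict(self, items: Iterable[str]) -> "Partition":
        """Partition restricted to ``items`` (isolates filtered likewise)."""
        keep = set(items)
        return Partition(
            {it: m for it, m in self.membership.items() if it in keep},
            frozenset(i for i in self.isolates if i in keep),
        )

    def relabeled(self) -> "Partition":
        """Canonical module ids: 1..K in order of each module's smallest item."""
        reps = {m: min(its) for m, its in self.modules.items()}
        order = sorted(reps, key=lambda m: reps[m])
        remap = {m: i + 1 for i, m in enumerate(order)}
        return Partition({it: remap[m] for it, m in self.membership.items()}, self.isolates)

    def to_frame(self) -> pd.DataFrame:
        rows = [(it, mod) for it, mod in sorted(self.membership.items())]
        rows += [(it, "") for it in sorted(self.isolates)]
        return pd.DataFrame(rows, columns=["item", "cluster"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Partition":
        df = pd.read_csv(path, dtype={"item": str}, keep_default_na=False)
        membership = {
            r.item: r.cluster for r in df.itertuples() if str(r.cluster) != ""
        }
        isolates = [r.item for r in df.itertuples() if str(r.cluster) == ""]
        return cls(membership, frozenset(isolates))
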