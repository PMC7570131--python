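"""Gene-set collections: GMT I/O, identifier mapping, universe restriction."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)


class GMTError(ValueError):
    """Raised for malformed GMT input."""


def _dedup(members) -> list[str]:
    seen = set()
    out = []
    for g in members:
        if g not in seen:
            seen.add(g)
            out.append(g)
    return out


@dataclass
class GeneSetCollection:
    """Named gene sets with provenance tags and an optional test universe."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    tags: dict[str, str] = field(default_factory=dict)
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        self.sets = {name: _dedup(m) for name, m in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def subset(self, names) -> "GeneSetCollection":
        return GeneSetCollection(
            sets={n: self.sets[n] for n in names},
            tags={n: self.tags.get(n, "custom") for n in names},
            universe=self.universe,
        )

    def by_tag(self, *tags: str) -> "GeneSetCollection":
        keep = [n for n in self.sets if self.tags.get(n, "custom") in tags]
        return self.subset(keep)

    def restrict_to_universe(self, universe, min_size: int = 5) -> "GeneSetCollection":
        """Intersect each set with ``universe``; drop sets below ``min_size``."""
        uni = set(universe)
        kept: dict[str, list[str]] = {}
        for name, members in self.sets.items():
            restricted = [g for g in members if g in uni]
            if len(restricted) >= min_size:
                kept[name] = restricted
            else:
                logger.info(
                    "dropping set %s: %d members in universe (< %d)",
                    name, len(restricted), min_size,
                )
        return GeneSetCollection(
            sets=kept,
            tags={n: self.tags.get(n, "custom") for n in kept},
            universe=sorted(uni),
        )


def read_gmt(path, tag: str = "custom") -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>member...`` per line."""
    sets: dict[str, list[str]] = {}
    tags: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTError(f"{path}:{lineno}: expected >= 3 tab-separated "
                               f"fields, got {len(fields)}")
            name = fields[0]
            sets[name] = _dedup(g for g in fields[2:] if g)
            tags[name] = tag
    return GeneSetCollection(sets=sets, tags=tags)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.tags.get(name, "custom")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_id_mapping(path) -> pd.DataFrame:
    """Two-column mapping TSV with a header: (source_id, target_id)."""
    tab = pd.read_csv(path, sep="\t", dtype=str)
    if tab.shape[1] < 2:
        raise ValueError(f"{path}: mapping needs two columns")
    tab = tab.iloc[:, :2]
    tab.columns = ["source_id", "target_id"]
    return tab.dropna()


def map_ids(collection: GeneSetCollection, mapping: pd.DataFrame) -> GeneSetCollection:
    """Translate member IDs through a (source, target) table.

    One-to-many mappings expand to all targets; members absent from the
    mapping are dropped (counted in the log).  Sets are de-duplicated after
    translation.
    """
    if len(mapping) == 0:
        raise ValueError("empty ID mapping")
    lut: dict[str, list[str]] = {}
    for src, tgt in zip(mapping.iloc[:, 0], mapping.iloc[:, 1]):
        lut.setdefault(str(src), []).append(str(tgt))
    mapped: dict[str, list[str]] = {}
    n_dropped = 0
    for name, members in collection.sets.items():
        out: list[str] = []
        for g in members:
            targets = lut.get(g)
            if targets is None:
                n_dropped += 1
            else:
                out.extend(targets)
        mapped[name] = _dedup(out)
    logger.info("ID mapping dropped %d unmapped members across %d sets",
                n_dropped, len(collection.sets))
    return GeneSetCollection(
        sets=mapped, tags=dict(collection.tags), universe=collection.universe
    )


def membership_matrix(collection: GeneSetCollection, universe) -> pd.DataFrame:
    """Boolean sets x universe indicator matrix (order = collection order)."""
    import numpy as np

    pos = {g: i for i, g in enumerate(universe)}
    mat = np.zeros((len(collection.sets), len(universe)), dtype=bool)
    for k, members in enumerate(collection.sets.values()):
        idx = [pos[g] for g in members if g in pos]
        mat[k, idx] = True
    return pd.DataFrame(mat, index=list(collection.sets), columns=list(universe))
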