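"""Balanced random-partition experimental designs.

The random partition design divides a pool of N species into disjoint
assemblages of size S (a richness level), for every richness level that
divides N, and repeats the process over P independent partitions.  Every
species therefore appears exactly P times at each richness level.  Each
assemblage is replicated K times and crossed with every temperature
treatment, giving T x K x P x sum_S(N/S) experimental units; with the
default 16 species, levels {1,2,4,8,16}, 5 partitions, 3 replicates and 3
temperatures that is 3 x 3 x 5 x 31 = 1395 units, 465 per temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd

SPECIES_SEP = ";"


@dataclass(frozen=True)
class Assemblage:
    """One community composition drawn within one partition."""

    assemblage_id: str
    partition: int
    richness: int
    species: frozenset

    def __post_init__(self):
        if len(self.species) != self.richness:
            raise ValueError(
                f"{self.assemblage_id}: |species| = {len(self.species)} "
                f"!= richness {self.richness}"
            )


class DesignTable:
    """The full set of experimental units, one row per microcosm well.

    Columns: unit_id, temperature_C, partition, richness, assemblage_id,
    replicate, species (semicolon-joined ids).
    """

    COLUMNS = [
        "unit_id", "temperature_C", "partition", "richness",
        "assemblage_id", "replicate", "species",
    ]

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def species_pool(self) -> List[str]:
        pool = set()
        for s in self.frame["species"]:
            pool.update(s.split(SPECIES_SEP))
        return sorted(pool)

    def species_sets(self) -> pd.Series:
        return self.frame["species"].map(
            lambda s: frozenset(s.split(SPECIES_SEP))
        )

    def presence_matrix(self) -> pd.DataFrame:
        """0/1 units x species matrix; row sums equal richness."""
        pool = self.species_pool
        sets = self.species_sets()
        data = {sp: [int(sp in st) for st in sets] for sp in pool}
        return pd.DataFrame(data, index=self.frame["unit_id"].tolist())

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DesignTable":
        return cls(pd.read_csv(path))


def generate_partition(
    pool: Sequence[str], richness: int, rng_seed
) -> List[Assemblage]:
    """Split the pool into disjoint assemblages of the given richness.

    The pool is shuffled once (sampling without replacement) and chunked,
    so the N/S assemblages are disjoint and jointly cover the pool.
    ``rng_seed`` may be an integer seed or a ``numpy.random.Generator``.
    """
    pool = list(pool)
    if len(set(pool)) != len(pool):
        raise ValueError("duplicate species ids in pool")
    n = len(pool)
    if richness < 1 or n % richness != 0:
        raise ValueError(
            f"richness {richness} does not divide the pool size {n}; the "
            f"random partition design requires a divisor richness level"
        )
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    order = [pool[i] for i in rng.permutation(n)]
    out = []
    for a, start in enumerate(range(0, n, richness)):
        members = frozenset(order[start : start + richness])
        out.append(
            Assemblage(
                assemblage_id=f"R{richness}-A{a + 1}",
                partition=0,
                richness=richness,
                species=members,
            )
        )
    return out


def generate_full_design(
    pool: Sequence[str],
    levels: Iterable[int] = (1, 2, 4, 8, 16),
    n_partitions: int = 5,
    n_replicates: int = 3,
    temperatures: Sequence[float] = (15.0, 25.0, 30.0),
    seed: int = 0,
) -> DesignTable:
    """Generate the complete crossed design.

    Partitions at different richness levels are drawn independently (a
    fresh shuffle per level per partition); each assemblage is replicated
    ``n_replicates`` times at every temperature.
    """
    pool = list(pool)
    if len(set(pool)) != len(pool):
        raise ValueError("duplicate species ids in pool")
    levels = sorted(set(int(s) for s in levels))
    for s in levels:
        if len(pool) % s != 0:
            raise ValueError(
                f"richness level {s} does not divide the pool size {len(pool)}"
            )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    rows = []
    for p in range(1, n_partitions + 1):
        for s in levels:
            for asmb in generate_partition(pool, s, rng):
                assemblage_id = f"P{p}-{asmb.assemblage_id}"
                species = SPECIES_SEP.join(sorted(asmb.species))
                for temp in temperatures:
                    for rep in range(1, n_replicates + 1):
                        rows.append(
                            {
                                "unit_id": f"T{temp:g}-{assemblage_id}-rep{rep}",
                                "temperature_C": float(temp),
                                "partition": p,
                                "richness": s,
                                "assemblage_id": assemblage_id,
                                "replicate": rep,
                                "species": species,
                            }
                        )
    frame = pd.DataFrame(rows, columns=DesignTable.COLUMNS)
    return DesignTable(frame)


@dataclass
class ValidationCheck:
    name: str
    passed: bool
    details: str = ""


@dataclass
class DesignValidation:
    checks: List[ValidationCheck] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def __str__(self) -> str:
        lines = []
        for c in self.checks:
            status = "PASS" if c.passed else "FAIL"
            line = f"[{status}] {c.name}"
            if c.details:
                line += f": {c.details}"
            lines.append(line)
        return "\n".join(lines)


def validate_design(design: DesignTable) -> DesignValidation:
    """Check the balance invariants of a random-partition design.

    Returns findings rather than raising: disjointness and coverage of
    each (partition, richness) layer, replicate counts per assemblage x
    temperature, and the per-species balance (each species appears in
    exactly n_partitions assemblages per richness level).
    """
    frame = design.frame
    pool = design.species_pool
    report = DesignValidation()
    sets = design.species_sets()

    # one composition per assemblage id
    comp = frame.assign(_set=sets).groupby("assemblage_id")["_set"].nunique()
    bad = comp[comp > 1].index.tolist()
    report.checks.append(
        ValidationCheck(
            "assemblage composition consistency",
            not bad,
            f"assemblages with >1 composition: {bad}" if bad else "",
        )
    )

    # disjointness + coverage within each partition x richness layer
    offenders = []
    layer = frame.drop_duplicates("assemblage_id").assign(_set=lambda d: (
        d["species"].map(lambda s: frozenset(s.split(SPECIES_SEP)))))
    for (p, s), grp in layer.groupby(["partition", "richness"]):
        union: set = set()
        total = 0
        for st in grp["_set"]:
            union |= st
            total += len(st)
        if total != len(union) or union != set(pool):
            offenders.append(f"partition {p}, richness {s}")
    report.checks.append(
        ValidationCheck(
            "partition disjointness and coverage",
            not offenders,
            "; ".join(offenders),
        )
    )

    # replicate counts per assemblage x temperature
    counts = frame.groupby(["assemblage_id", "temperature_C"]).size()
    expected = counts.mode().iat[0] if len(counts) else 0
    bad_rep = counts[counts != expected]
    report.checks.append(
        ValidationCheck(
            "replicate counts per assemblage x temperature",
            bad_rep.empty,
            ", ".join(f"{a} @ {t:g}C has {k} (expected {expected})"
                      for (a, t), k in bad_rep.items()),
        )
    )

    # per-species balance: appearances per richness level, per species
    layer_counts = {}
    for _, row in layer.iterrows():
        for sp in row["_set"]:
            layer_counts[(row["richness"], sp)] = (
                layer_counts.get((row["richness"], sp), 0) + 1
            )
    per_level = {}
    for (s, sp), k in layer_counts.items():
        per_level.setdefault(s, []).append((sp, k))
    unbalanced = []
    for s, pairs in per_level.items():
        ks = {k for _, k in pairs}
        missing = set(pool) - {sp for sp, _ in pairs}
        if len(ks) > 1 or missing:
            unbalanced.append(
                f"richness {s}: counts {sorted(ks)}"
                + (f", missing {sorted(missing)}" if missing else "")
            )
    report.checks.append(
        ValidationCheck(
            "per-species balance across partitions",
            not unbalanced,
            "; ".join(unbalanced),
        )
    )
    return report
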