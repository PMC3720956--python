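"""Hierarchical partitioning of explanatory power.

Given Nagelkerke R^2 of the abiotic-only (ABIOT), biotic-only (BIOT)
and combined (FULL) models of one response, the FULL explanatory power
splits into

    pure_abiotic = R2_FULL - R2_BIOT
    pure_biotic  = R2_FULL - R2_ABIOT
    joint        = R2_ABIOT + R2_BIOT - R2_FULL

an exact identity (the three components sum to R2_FULL).  Components
computed from rounded inputs can dip slightly below zero; they are
flagged, never clipped, so the identity is preserved.

A packaged fixture (``data/table3_r2.csv``) carries the 16 published
R^2 triplets of the tiger-beetle case study (8 data sets x PA/AB) for
the grouped mean +/- SD summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

NEGATIVITY_FLAG = -0.01  # below this a component is flagged, not corrected


@dataclass(frozen=True)
class PartitionTriple:
    pure_abiotic: float
    pure_biotic: float
    joint: float
    flagged: bool = False  # a component < -0.01 (rounded-input artefact)

    @property
    def total(self) -> float:
        return self.pure_abiotic + self.pure_biotic + self.joint


def partition(r2_abiot: float, r2_biot: float, r2_full: float
              ) -> PartitionTriple:
    """Split R2_FULL into pure-abiotic, pure-biotic and joint parts."""
    for name, v in (("ABIOT", r2_abiot), ("BIOT", r2_biot), ("FULL", r2_full)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"R^2 {name}={v} outside [0, 1]")
    pure_a = r2_full - r2_biot
    pure_b = r2_full - r2_abiot
    joint = r2_abiot + r2_biot - r2_full
    flagged = min(pure_a, pure_b, joint) < NEGATIVITY_FLAG
    return PartitionTriple(pure_a, pure_b, joint, flagged)


# data-set id groupings of the two-location, four-scale design
_GROUPERS = {
    "all": lambda ds, resp: "all",
    "by-location": lambda ds, resp: "A" if ds % 2 == 1 else "B",
    "by-scale": lambda ds, resp: {1: "trap", 2: "trap", 3: "1m", 4: "1m",
                                  5: "50cm", 6: "50cm", 7: "25cm",
                                  8: "25cm"}[ds],
    "by-stage": lambda ds, resp: "adult" if ds in (1, 2) else "larva",
    "by-stage-scale": lambda ds, resp: (
        "adult" if ds in (1, 2) else
        {3: "larva-1m", 4: "larva-1m", 5: "larva-50cm", 6: "larva-50cm",
         7: "larva-25cm", 8: "larva-25cm"}[ds]),
}


def summarize_partitions(triples: list[tuple[int, str, PartitionTriple]],
                         grouping: str = "all") -> pd.DataFrame:
    """Mean and sample (n-1) SD of each partition component per group.

    ``triples`` holds (data-set id, response label, PartitionTriple).
    Groupings: all | by-location (odd ids = A, even = B) | by-scale |
    by-stage | by-stage-scale.
    """
    if grouping not in _GROUPERS:
        raise ValueError(f"unknown grouping {grouping!r}")
    key = _GROUPERS[grouping]
    rows = []
    for ds, resp, t in triples:
        rows.append({"group": key(ds, resp), "dataset": ds, "response": resp,
                     "pure_abiotic": t.pure_abiotic,
                     "pure_biotic": t.pure_biotic, "joint": t.joint})
    df = pd.DataFrame(rows)
    out = []
    for g, sub in df.groupby("group", sort=True):
        if len(sub) == 0:
            continue
        rec: dict[str, object] = {"group": g, "n": len(sub)}
        for comp in ("pure_abiotic", "pure_biotic", "joint"):
            rec[f"{comp}_mean"] = float(sub[comp].mean())
            rec[f"{comp}_sd"] = (float(sub[comp].std(ddof=1))
                                 if len(sub) > 1 else 0.0)
        out.append(rec)
    return pd.DataFrame(out)


def load_published_r2() -> pd.DataFrame:
    """The packaged 16-row fixture of published (ABIOT, BIOT, FULL)
    Nagelkerke R^2 triplets: columns dataset, response, ABIOT, BIOT, FULL."""
    with resources.files("stageniche.data").joinpath(
            "table3_r2.csv").open() as fh:
        return pd.read_csv(fh)


def partition_table(r2_table: pd.DataFrame) -> list[tuple[int, str,
                                                          PartitionTriple]]:
    """Partition every row of a (dataset, response, ABIOT, BIOT, FULL)
    R^2 table."""
    return [
        (int(r.dataset), str(r.response),
         partition(float(r.ABIOT), float(r.BIOT), float(r.FULL)))
        for r in r2_table.itertuples(index=False)]


def summarize_fit(r2_table: pd.DataFrame, column: str = "BIOT",
                  grouping: str = "by-stage-scale") -> pd.DataFrame:
    """Grouped mean +/- sample SD of one model column of an R^2 table."""
    if grouping not in _GROUPERS:
        raise ValueError(f"unknown grouping {grouping!r}")
    key = _GROUPERS[grouping]
    df = r2_table.copy()
    df["group"] = [key(int(ds), str(resp))
                   for ds, resp in zip(df["dataset"], df["response"])]
    out = []
    for g, sub in df.groupby("group", sort=True):
        out.append({"group": g, "n": len(sub),
                    "mean": float(sub[column].mean()),
                    "sd": float(sub[column].std(ddof=1))
                    if len(sub) > 1 else 0.0})
    return pd.DataFrame(out)
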