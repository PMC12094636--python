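"""Hypergeometric over-representation analysis (ORA).

A significant-gene list is tested against user-supplied gene sets (GMT
format, e.g. cortical-layer marker sets) with the one-sided hypergeometric
upper-tail test, BH-FDR corrected across sets.  The background universe is
the full tested gene population (all genes in the expression matrix).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from gseapy import read_gmt
from scipy.stats import hypergeom

from .groupstats import bh_fdr

__all__ = ["GeneSetCollection", "write_gmt", "hypergeometric_ora"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets intersected with a background universe.

    Sets that are empty after intersection with the background are dropped
    with a logged warning.
    """

    sets: dict[str, tuple[str, ...]]
    background: frozenset[str]

    @classmethod
    def from_dict(
        cls, sets: Mapping[str, Iterable[str]], background: Iterable[str]
    ) -> "GeneSetCollection":
        bg = frozenset(background)
        kept: dict[str, tuple[str, ...]] = {}
        for name, genes in sets.items():
            inter = tuple(sorted(set(genes) & bg))
            if not inter:
                logger.warning(
                    "gene set %r is empty after intersecting the background; dropped",
                    name,
                )
                continue
            kept[name] = inter
        return cls(sets=kept, background=bg)

    @classmethod
    def from_gmt(cls, path: str | Path, background: Iterable[str]) -> "GeneSetCollection":
        return cls.from_dict(read_gmt(str(path)), background)


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              description: str = "na") -> None:
    """Write gene sets in the standard tab-separated GMT layout."""
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def hypergeometric_ora(
    hits: Sequence[str], collection: GeneSetCollection, alpha: float = 0.05
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per gene set.

    Hits outside the background are dropped with a log message; an empty hit
    list is an error.  Returns per set: overlap, expected overlap under the
    null, odds ratio, p, BH-FDR-adjusted p and the significance flag.
    """
    hit_set = set(hits)
    if not hit_set:
        raise ValueError("empty hit list")
    outside = hit_set - collection.background
    if outside:
        logger.info("dropping %d hits outside the background", len(outside))
        hit_set -= outside
    if not hit_set:
        raise ValueError("no hits remain within the background universe")
    n_bg = len(collection.background)
    n_hits = len(hit_set)
    rows = []
    for name, genes in collection.sets.items():
        k_set = len(genes)
        overlap = len(hit_set & set(genes))
        expected = n_hits * k_set / n_bg
        p = float(hypergeom.sf(overlap - 1, n_bg, k_set, n_hits))
        a, b = overlap, n_hits - overlap
        c, d = k_set - overlap, n_bg - k_set - n_hits + overlap
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append(
            {
                "set_name": name,
                "set_size": k_set,
                "overlap": overlap,
                "expected": expected,
                "odds_ratio": odds,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["p_fdr"] < alpha
    return out
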