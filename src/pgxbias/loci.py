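"""Locus calling from summary statistics by greedy distance clumping.

Variants passing the suggestive threshold are clumped: repeatedly the
smallest-p unassigned variant becomes a lead and absorbs every unassigned
passing variant within +/- 0.5 Mb on its chromosome.  Loci whose lead p is
below the genome-wide threshold are tier "genome-wide", the rest
"suggestive".  Ties in p break by position, so the procedure is
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Locus", "call_loci", "loci_to_frame"]

GENOME_WIDE_P = 5e-8
SUGGESTIVE_P = 1e-5
LOCUS_WINDOW_BP = 500_000


@dataclass
class Locus:
    lead_variant: str
    chrom: str
    pos: int
    p: float
    tier: str
    members: list[str] = field(default_factory=list)
    span: int = 0


def call_loci(
    results: pd.DataFrame,
    sig: float = GENOME_WIDE_P,
    sug: float = SUGGESTIVE_P,
    window: int = LOCUS_WINDOW_BP,
) -> list[Locus]:
    """Greedy clumping of a summary table with ``variant, chrom, pos, p``."""
    for col in ("variant", "chrom", "pos", "p"):
        if col not in results.columns:
            raise ValueError(f"missing required column {col!r}")
    hits = results[np.isfinite(results["p"]) & (results["p"] < sug)]
    hits = hits.sort_values(["p", "chrom", "pos"], kind="stable").reset_index(drop=True)
    assigned = np.zeros(len(hits), dtype=bool)
    loci: list[Locus] = []
    for i in range(len(hits)):
        if assigned[i]:
            continue
        lead = hits.iloc[i]
        near = (
            (~assigned)
            & (hits["chrom"] == lead["chrom"]).to_numpy()
            & (np.abs(hits["pos"].to_numpy() - lead["pos"]) <= window)
        )
        members = hits.loc[near]
        assigned |= near
        loci.append(
            Locus(
                lead_variant=str(lead["variant"]),
                chrom=str(lead["chrom"]),
                pos=int(lead["pos"]),
                p=float(lead["p"]),
                tier="genome-wide" if lead["p"] < sig else "suggestive",
                members=list(members["variant"]),
                span=int(members["pos"].max() - members["pos"].min()),
            )
        )
    loci.sort(key=lambda l: (l.chrom, l.pos))
    return loci


def loci_to_frame(loci: list[Locus]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lead_variant": [l.lead_variant for l in loci],
            "chrom": [l.chrom for l in loci],
            "pos": [l.pos for l in loci],
            "p": [l.p for l in loci],
            "tier": [l.tier for l in loci],
            "n_members": [len(l.members) for l in loci],
            "span": [l.span for l in loci],
        }
    )
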