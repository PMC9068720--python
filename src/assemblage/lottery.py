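"""Competitive lottery model: clade winner detection, prevalence, diversity.

Within a taxonomic clade (genus), a 'winner' in a sample is a member holding
more than 90% of the clade's within-sample abundance (a strong priority
effect: only one species occupies the niche space).  Per clade and time group
the model reports winner prevalence (fraction of clade-present samples with a
winner) and winner diversity (Shannon entropy of winner identities across
samples, normalized to [0, 1]); a clade is flagged strongly lottery-like when
prevalence > 0.75 and diversity > 0.25.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import CountTable

logger = logging.getLogger("assemblage")

__all__ = ["build_clades", "detect_winner", "winner_prevalence",
           "winner_diversity", "lottery_report", "LotteryReport"]

PREVALENCE_FLAG = 0.75
DIVERSITY_FLAG = 0.25


def build_clades(tax: dict[str, dict[str, str]], table: CountTable,
                 min_clade_otus: int = 2, min_clade_relabund: float = 0.0
                 ) -> dict[str, list[str]]:
    """Partition the table's OTUs into genus clades.

    OTUs without a genus annotation are excluded (count logged).  Clades with
    fewer than ``min_clade_otus`` members are retained (single-member winners
    are structurally forced but still reported) — callers may treat them as
    trivial.  ``min_clade_relabund`` drops clades whose mean relative
    abundance over samples is below the floor.
    """
    clades: dict[str, list[str]] = {}
    unannotated = 0
    for otu in table.otu_ids:
        genus = tax.get(otu, {}).get("genus")
        if genus:
            clades.setdefault(genus, []).append(otu)
        else:
            unannotated += 1
    if unannotated:
        logger.info("build_clades: %d OTU(s) without genus annotation excluded",
                    unannotated)
    if min_clade_relabund > 0:
        rel = table.relative()
        clades = {g: mem for g, mem in clades.items()
                  if rel[mem].sum(axis=1).mean() >= min_clade_relabund}
    if not clades:
        raise ValueError("no genus clades could be built")
    return dict(sorted(clades.items()))


def detect_winner(clade_abundances: pd.Series, threshold: float = 0.9
                  ) -> str | None:
    """The clade member holding strictly more than ``threshold`` of the
    clade's within-sample total, or None."""
    total = clade_abundances.sum()
    if total <= 0:
        raise ValueError("clade absent from sample; exclude from denominator")
    frac = clade_abundances / total
    top = frac.idxmax()
    return top if frac.loc[top] > threshold else None


def winner_prevalence(win_records: list[str | None]) -> float:
    """Fraction of evaluated (clade-present) samples having a winner."""
    if not win_records:
        raise ValueError("no evaluated samples")
    return sum(1 for w in win_records if w is not None) / len(win_records)


def winner_diversity(win_records: list[str | None]) -> float:
    """Normalized Shannon entropy of winner identities across samples.

    0 when a single OTU wins everywhere (by convention), approaching 1 when
    wins are spread evenly over the distinct winning OTUs.
    """
    winners = [w for w in win_records if w is not None]
    if not winners:
        raise ValueError("no wins recorded")
    counts = pd.Series(winners).value_counts().to_numpy(dtype=float)
    if len(counts) == 1:
        return 0.0
    p = counts / counts.sum()
    h = -(p * np.log(p)).sum()
    return float(h / np.log(len(counts)))


@dataclass
class LotteryReport:
    """Per clade x time group lottery statistics."""

    table: pd.DataFrame  # clade, time_group, n_otus, n_samples_evaluated,
    #                      prevalence, diversity, winners, lottery_like
    threshold: float
    presence_floor: float


def lottery_report(table: CountTable, tax: dict[str, dict[str, str]],
                   metadata: pd.DataFrame, threshold: float = 0.9,
                   presence_floor: float = 0.001,
                   by: str = "time_point") -> LotteryReport:
    """Winner prevalence/diversity per clade and time group.

    A clade is evaluated in a sample only when it holds at least
    ``presence_floor`` of the sample's relative abundance.  Single-OTU clades
    are reported but never flagged lottery-like (their winner is forced).
    """
    if by not in metadata.columns:
        raise ValueError(f"metadata lacks column {by!r}")
    clades = build_clades(tax, table)
    rel = table.relative()
    meta = metadata.reindex(table.sample_ids)
    if meta[by].isna().any():
        raise ValueError("every sample needs metadata")
    records = []
    time_groups = list(meta[by].cat.categories) if hasattr(meta[by], "cat") \
        else sorted(meta[by].unique())
    for genus, members in clades.items():
        sub = rel[members]
        clade_tot = sub.sum(axis=1)
        for tg in time_groups:
            sids = meta.index[meta[by] == tg]
            evaluated = [s for s in sids if clade_tot.loc[s] >= presence_floor]
            if not evaluated:
                records.append((genus, tg, len(members), 0, np.nan, np.nan,
                                "", False))
                continue
            wins = [detect_winner(sub.loc[s], threshold) for s in evaluated]
            prev = winner_prevalence(wins)
            named = [w for w in wins if w is not None]
            div = winner_diversity(wins) if named else np.nan
            win_counts = pd.Series(named).value_counts() if named else pd.Series(dtype=int)
            win_str = ";".join(f"{o}:{c}" for o, c in win_counts.items())
            flag = (len(members) >= 2 and prev > PREVALENCE_FLAG
                    and not np.isnan(div) and div > DIVERSITY_FLAG)
            records.append((genus, tg, len(members), len(evaluated),
                            prev, div, win_str, flag))
    df = pd.DataFrame(records, columns=["clade", "time_group", "n_otus",
                                        "n_samples_evaluated", "prevalence",
                                        "diversity", "winners", "lottery_like"])
    return LotteryReport(table=df, threshold=threshold,
                         presence_floor=presence_floor)
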