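"""Connectivity-map style signature-reversal scoring of compounds.

A phenotype is summarised by an up/down gene signature; each compound by a
reference profile ranking all genes from most up-regulated (rank 1) to most
down-regulated (rank n) after treatment.  For each tag list a signed
Kolmogorov-Smirnov-like statistic measures whether the tags cluster at the
top (positive) or the bottom (negative) of the ranking:

    a = max_j ( j/t - V(j)/n ),   b = max_j ( V(j)/n - (j-1)/t )

with V(j) the profile rank of the j-th tag (tags ordered by rank) and the
statistic a if a > b else -b.  The raw connectivity score is
s = ks_up - ks_down when the two statistics disagree in sign, else 0:
positive s means the compound mimics the phenotype, negative s that it
reverses it.  Scores are normalised batch-wise to [-1, 1] (positives by the
max positive, negatives by the magnitude of the most negative) and
candidate drugs are the most-negative top_k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Signature", "build_signature", "ks_statistic", "connectivity_score",
    "score_compounds", "normalize_and_rank",
]

logger = logging.getLogger(__name__)


@dataclass
class Signature:
    up: list[str]
    down: list[str]

    def __post_init__(self):
        overlap = set(self.up) & set(self.down)
        if overlap:
            raise ValueError(f"features in both lists: {sorted(overlap)[:5]}")
        if not self.up or not self.down:
            raise ValueError("both up and down lists must be non-empty")


def build_signature(key_molecules, de_results: pd.DataFrame) -> Signature:
    """Split measured key genes by fold-change sign into up/down tag lists.

    miRNAs are excluded (signatures are gene-based); molecules without a
    measured fold change, and genes with log2FC exactly 0, are dropped.
    """
    de = de_results.set_index("feature_id")
    up, down, skipped = [], [], 0
    for mol in key_molecules:
        if mol not in de.index or de.loc[mol, "molecule_type"] == "miRNA":
            skipped += 1
            continue
        lfc = float(de.loc[mol, "log2fc"])
        if lfc > 0:
            up.append(mol)
        elif lfc < 0:
            down.append(mol)
    if skipped:
        logger.info("%d key molecules without usable expression excluded", skipped)
    return Signature(up, down)


def ks_statistic(tags, profile_ranks: pd.Series | dict) -> float:
    """Signed KS statistic of a tag list against one compound's ranking.

    ``profile_ranks`` maps feature id -> rank (a permutation of 1..n).
    """
    ranks = pd.Series(profile_ranks)
    missing = set(tags) - set(ranks.index)
    if missing:
        raise ValueError(f"tag(s) absent from profile: {sorted(missing)[:5]}")
    t = len(tags)
    if t == 0:
        raise ValueError("empty tag list")
    n = len(ranks)
    v = np.sort(ranks.loc[list(tags)].to_numpy(dtype=float))
    j = np.arange(1, t + 1)
    a = float(np.max(j / t - v / n))
    b = float(np.max(v / n - (j - 1) / t))
    return a if a > b else -b


def connectivity_score(sig: Signature, profile_ranks) -> tuple[float, float, float]:
    """(ks_up, ks_down, raw score); the score is 0 when both tails agree in sign."""
    ks_up = ks_statistic(sig.up, profile_ranks)
    ks_down = ks_statistic(sig.down, profile_ranks)
    s = 0.0 if np.sign(ks_up) == np.sign(ks_down) else ks_up - ks_down
    return ks_up, ks_down, s


def score_compounds(sig: Signature, profiles: pd.DataFrame) -> pd.DataFrame:
    """Raw connectivity scores for every compound in a long-format profile table.

    ``profiles`` columns: compound_id, feature_id, rank.  Signature features
    missing from a given profile are dropped for that profile (logged); an
    error is raised only if a tag list empties entirely.
    """
    rows = []
    for cid, group in sorted(profiles.groupby("compound_id")):
        ranks = group.set_index("feature_id")["rank"]
        feats = set(ranks.index)
        up = [f for f in sig.up if f in feats]
        down = [f for f in sig.down if f in feats]
        n_drop = (len(sig.up) - len(up)) + (len(sig.down) - len(down))
        if n_drop:
            logger.info("compound %s: %d signature features not in profile",
                        cid, n_drop)
        ks_up, ks_down, s = connectivity_score(Signature(up, down), ranks)
        rows.append((cid, ks_up, ks_down, s))
    return pd.DataFrame(rows, columns=["compound_id", "ks_up", "ks_down", "raw"])


def normalize_and_rank(results: pd.DataFrame, top_k: int = 10) -> pd.DataFrame:
    """Batch-normalise raw scores to [-1, 1] and return the top_k most negative.

    Positive raws divide by the batch maximum, negative raws by the
    magnitude of the batch minimum; rank 1 is the strongest predicted
    reversal.
    """
    raw = results["raw"].to_numpy(dtype=float)
    if np.all(raw == 0):
        raise ValueError("all connectivity scores are zero; nothing to rank")
    pos_max = raw[raw > 0].max() if np.any(raw > 0) else 1.0
    neg_min = raw[raw < 0].min() if np.any(raw < 0) else -1.0
    norm = np.where(raw > 0, raw / pos_max, raw / abs(neg_min))
    out = results.copy()
    out["normalized"] = norm
    out = out.sort_values(["normalized", "compound_id"]).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    if top_k > len(out):
        logger.warning("top_k=%d exceeds %d compounds; returning all",
                       top_k, len(out))
        top_k = len(out)
    return out.head(top_k)
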