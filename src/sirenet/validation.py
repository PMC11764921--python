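"""Edge-reliability validation against protein-interaction evidence scores.

Each undirected gene pair carries per-channel evidence scores in [0, 1)
(coexpression, experimental, curated database, text mining, homology).  The
channels are combined into a single reliability score by the published STRING
scheme: remove the prior p = 0.041 from every channel, take the probabilistic
union (noisy-OR) of the corrected channels, add the prior back once, and cap
at 0.999:

    s'        = max(0, (s - p) / (1 - p))        per nonzero channel
    combined' = 1 - prod(1 - s')
    combined  = min(0.999, combined' + p * (1 - combined'))

Homology-corrected channels are not reproducible from the per-channel table
alone, so pairs with a nonzero homology score fall back to their printed
combined score during validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .network_model import SignedNetwork

__all__ = [
    "ChannelScores",
    "EdgeReliability",
    "ReliabilityReport",
    "STRING_PRIOR",
    "string_combined_score",
    "validate_edge_reliability",
]

STRING_PRIOR = 0.041
_CHANNELS = ("coexpression", "experimental", "database", "textmining")


@dataclass(frozen=True)
class ChannelScores:
    """Per-channel evidence for one undirected gene pair."""

    node1: str
    node2: str
    homology: float = 0.0
    coexpression: float = 0.0
    experimental: float = 0.0
    database: float = 0.0
    textmining: float = 0.0
    combined: float | None = None  # printed combined score, if available

    def __post_init__(self) -> None:
        for ch in ("homology",) + _CHANNELS:
            v = getattr(self, ch)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"channel {ch} must be in [0, 1), got {v}")

    @property
    def pair(self) -> frozenset[str]:
        return frozenset({self.node1, self.node2})


@dataclass(frozen=True)
class EdgeReliability:
    source: str
    target: str
    sign: int
    combined: float
    passed: bool
    recomputed: bool


@dataclass(frozen=True)
class ReliabilityReport:
    edges: tuple[EdgeReliability, ...]
    unmatched_edges: tuple[tuple[str, str, int], ...]
    unmatched_scores: tuple[frozenset[str], ...]
    threshold: float

    @property
    def n_passed(self) -> int:
        return sum(e.passed for e in self.edges)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "source": e.source,
                    "target": e.target,
                    "sign": e.sign,
                    "combined": e.combined,
                    "passed": e.passed,
                    "recomputed": e.recomputed,
                }
                for e in self.edges
            ],
            columns=["source", "target", "sign", "combined", "passed", "recomputed"],
        )


def string_combined_score(
    channels: ChannelScores | dict[str, float],
    prior: float = STRING_PRIOR,
    cap: float = 0.999,
) -> float:
    """Prior-corrected noisy-OR combination of evidence channels.

    Monotone nondecreasing in every channel; a single channel equal to the
    prior contributes nothing; the result never exceeds ``cap``.  Raises for a
    nonzero homology channel (homology discounting of the other channels is
    not supported — use the printed combined score for such pairs).
    """
    if isinstance(channels, ChannelScores):
        values = {ch: getattr(channels, ch) for ch in _CHANNELS}
        homology = channels.homology
    else:
        values = {ch: float(channels.get(ch, 0.0)) for ch in _CHANNELS}
        homology = float(channels.get("homology", 0.0))
    if homology > 0:
        raise ValueError(
            "nonzero homology channel is unsupported; use the printed combined score"
        )
    survive = 1.0
    for s in values.values():
        if s > 0:
            corrected = max(0.0, (s - prior) / (1.0 - prior))
            survive *= 1.0 - corrected
    combined = 1.0 - survive
    return min(cap, combined + prior * (1.0 - combined))


def _scores_from_frame(table: pd.DataFrame) -> list[ChannelScores]:
    cols = {c.lower(): c for c in table.columns}
    out = []
    for _, row in table.iterrows():
        out.append(
            ChannelScores(
                node1=str(row[cols["node1"]]),
                node2=str(row[cols["node2"]]),
                homology=float(row[cols.get("homology", "homology")]) if "homology" in cols else 0.0,
                coexpression=float(row[cols["coexpression"]]) if "coexpression" in cols else 0.0,
                experimental=float(row[cols["experimental"]]) if "experimental" in cols else 0.0,
                database=float(row[cols["database"]]) if "database" in cols else 0.0,
                textmining=float(row[cols["textmining"]]) if "textmining" in cols else 0.0,
                combined=float(row[cols["combined"]]) if "combined" in cols else None,
            )
        )
    return out


def validate_edge_reliability(
    net: SignedNetwork,
    scores: list[ChannelScores] | pd.DataFrame,
    threshold: float = 0.9,
) -> ReliabilityReport:
    """Match network edges against evidence-score rows and flag reliable ones.

    Matching is undirected and sign-blind (reliability concerns the existence
    of an interaction, not its direction).  Pairs with zero homology get a
    recomputed combined score; nonzero-homology pairs use the printed one.
    Edges without any score row and score rows without a network edge are
    listed separately.
    """
    if isinstance(scores, pd.DataFrame):
        scores = _scores_from_frame(scores)
    by_pair: dict[frozenset[str], ChannelScores] = {s.pair: s for s in scores}

    edges: list[EdgeReliability] = []
    unmatched_edges: list[tuple[str, str, int]] = []
    matched_pairs: set[frozenset[str]] = set()
    for src, tgt, sign in sorted(net.edges):
        pair = frozenset({src, tgt})
        row = by_pair.get(pair)
        if row is None:
            unmatched_edges.append((src, tgt, sign))
            continue
        matched_pairs.add(pair)
        if row.homology > 0:
            if row.combined is None:
                raise ValueError(
                    f"pair {sorted(pair)} has nonzero homology and no printed combined score"
                )
            combined, recomputed = row.combined, False
        else:
            combined, recomputed = round(string_combined_score(row), 3), True
        edges.append(
            EdgeReliability(
                source=src,
                target=tgt,
                sign=sign,
                combined=combined,
                passed=combined >= threshold,
                recomputed=recomputed,
            )
        )
    unmatched_scores = tuple(
        sorted((p for p in by_pair if p not in matched_pairs), key=sorted)
    )
    return ReliabilityReport(
        edges=tuple(edges),
        unmatched_edges=tuple(unmatched_edges),
        unmatched_scores=unmatched_scores,
        threshold=threshold,
    )
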