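"""AU-rich element (ARE) scoring of 3'UTR sequences.

AREs are built on AUUUA pentamers, often overlapping or clustered, and
recruit regulatory RNA-binding proteins (ZFP36/TTP family, ELAVL1, TIA1).
The scoring scheme is additive: every pentamer contributes a base score,
consecutive pentamers in close proximity earn a pair bonus that decays
with the gap between them, and pentamers embedded in an AU-rich context
earn a further bonus. All weights live in :class:`AREScoreParams` and can
be loaded from YAML, so the scheme is a data question rather than a code
change; the packaged defaults are in ``data/arescore_defaults.yaml``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import yaml

__all__ = ["AREScoreParams", "AREScoreResult", "find_pentamers", "score", "score_fasta"]

_VALID = set("ACGTN")


@dataclass(frozen=True)
class AREScoreParams:
    motif: str = "AUUUA"
    base_score: float = 1.0
    # (max_gap, bonus): gap = nt between the end of one pentamer and the
    # start of the next (negative for overlapping pentamers). The first
    # matching entry wins; entries must be sorted by max_gap.
    pair_bonuses: tuple[tuple[int, float], ...] = ((2, 1.5), (10, 0.75))
    au_context_bonus: float = 0.5
    au_context_window: int = 20
    au_context_fraction: float = 0.75

    def __post_init__(self):
        if self.base_score <= 0:
            raise ValueError("base_score must be positive")
        if any(b < 0 for _, b in self.pair_bonuses) or self.au_context_bonus < 0:
            raise ValueError("bonuses must be nonnegative")
        gaps = [g for g, _ in self.pair_bonuses]
        if gaps != sorted(gaps):
            raise ValueError("pair_bonuses must be sorted by max_gap")

    @classmethod
    def from_yaml(cls, path) -> "AREScoreParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["pair_bonuses"] = tuple((int(g), float(b)) for g, b in raw.get("pair_bonuses", ()))
        return cls(**raw)

    @classmethod
    def default(cls) -> "AREScoreParams":
        with resources.as_file(
            resources.files("translatome.data").joinpath("arescore_defaults.yaml")
        ) as p:
            return cls.from_yaml(p)


@dataclass(frozen=True)
class AREScoreResult:
    gene_id: str
    n_pentamers: int
    score: float


def _normalize(seq: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - _VALID
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    return s


def find_pentamers(seq: str, params: AREScoreParams | None = None) -> list[int]:
    """All 0-based start positions of the motif, overlapping occurrences included.

    T and U are equivalent and matching is case-insensitive; N never
    matches.
    """
    params = params or AREScoreParams()
    s = _normalize(seq)
    motif = _normalize(params.motif)
    positions = []
    i = s.find(motif)
    while i != -1:
        positions.append(i)
        i = s.find(motif, i + 1)
    return positions


def score(seq: str, params: AREScoreParams | None = None, gene_id: str = "") -> AREScoreResult:
    """Additive ARE score of one sequence.

    ``score = base * n_pentamers + sum of pair bonuses over consecutive
    pentamer pairs + AU-context bonus for each pentamer whose flanks
    (within ``au_context_window`` nt on each side) exceed the AU-fraction
    threshold``. Zero pentamers always give score 0.
    """
    params = params or AREScoreParams()
    s = _normalize(seq)
    positions = find_pentamers(s, params)
    k = len(params.motif)
    total = params.base_score * len(positions)
    for prev, nxt in zip(positions, positions[1:]):
        gap = nxt - (prev + k)
        for max_gap, bonus in params.pair_bonuses:
            if gap <= max_gap:
                total += bonus
                break
    if params.au_context_bonus > 0:
        w = params.au_context_window
        for pos in positions:
            left = s[max(0, pos - w) : pos]
            right = s[pos + k : pos + k + w]
            # fixed denominator 2w: absent flank and N count as non-AU,
            # which keeps scores additive across long non-AU spacers
            if sum(c in "AT" for c in left + right) / (2 * w) >= params.au_context_fraction:
                total += params.au_context_bonus
    if not positions:
        total = 0.0
    return AREScoreResult(gene_id, len(positions), total)


def score_fasta(records, params: AREScoreParams | None = None) -> "pd.DataFrame":
    """Score an iterable of (gene_id, sequence) pairs into a tidy frame."""
    import pandas as pd

    params = params or AREScoreParams()
    rows = [score(seq, params, gene_id=gid) for gid, seq in records]
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in rows],
            "n_pentamers": [r.n_pentamers for r in rows],
            "score": [r.score for r in rows],
        }
    )
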