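"""Species-level assignment of short amplicon variants by global-alignment
identity against longer labeled references, with a near-tie multi-match
rule: every reference within 0.05 identity of the best hit is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import Align

DEFAULT_DELTA = 0.05


@dataclass
class Match:
    reference_id: str
    species: str
    identity: float


@dataclass
class MatchReport:
    query_id: str
    matches: list                 # all references, identity descending
    reported: list                # best + near-ties under the delta rule
    delta_to_runner_up: float

    def best(self) -> Match:
        return self.reported[0]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(self.query_id, m.reference_id, m.species, m.identity,
              m in self.reported) for m in self.matches],
            columns=["query", "reference", "species", "identity", "reported"],
        )


def _aligner(match: float, mismatch: float, gap_open: float,
             gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def global_identity(query: str, reference: str, match: float = 1.0,
                    mismatch: float = -1.0, gap_open: float = -2.0,
                    gap_extend: float = -1.0) -> float:
    """Needleman-Wunsch (affine-gap) identity: identical aligned positions
    divided by full alignment length, gap columns included in the
    denominator."""
    if not query or not reference:
        raise ValueError("empty sequence")
    aligner = _aligner(match, mismatch, gap_open, gap_extend)
    alignment = next(iter(aligner.align(query.upper(), reference.upper())))
    counts = alignment.counts()
    length = counts.gaps + counts.identities + counts.mismatches
    return counts.identities / length


def assign_species(query: str, references: dict, species_labels: dict,
                   delta: float = DEFAULT_DELTA, query_id: str = "query",
                   **scoring) -> MatchReport:
    """Rank references by global identity; report the best hit plus every
    reference whose identity is within ``delta`` of it.  Ties in identity
    are broken by reference id."""
    if not references:
        raise ValueError("need at least one reference")
    matches = [
        Match(rid, species_labels.get(rid, "unknown"),
              global_identity(query, seq, **scoring))
        for rid, seq in references.items()
    ]
    matches.sort(key=lambda m: (-m.identity, m.reference_id))
    best = matches[0].identity
    reported = [m for m in matches if best - m.identity < delta]
    runner_up = best - matches[1].identity if len(matches) > 1 else float("inf")
    return MatchReport(query_id, matches, reported, runner_up)


def assign_all(queries: dict, references: dict, species_labels: dict,
               delta: float = DEFAULT_DELTA, **scoring) -> list:
    return [assign_species(seq, references, species_labels, delta,
                           query_id=qid, **scoring)
            for qid, seq in queries.items()]
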