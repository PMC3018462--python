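"""Cross-platform probeset content mapping by exact full-length probe matching.

A probeset is considered *common* to the two platforms when 6 or more of its
probes (usually 11) occur with 100% identity over their entire length within
one single full-length sequence of the other platform. Because the rule
demands perfect full-length identity, an exact substring index is equivalent
to an alignment search and is bit-reproducible; reverse-complement hits
count toward the rule (an antisense probeset can legitimately match a sense
transcript), with the strand recorded.

The classification runs in two passes, mirroring a design/reference
asymmetry: first platform B's probesets are matched against platform A's
full sequences; then platform A's probesets are matched against the full
sequences of the platform-B probesets not yet marked common. In each pass a
qualifying match marks both the query probeset and every probeset backed by
the hit sequence as common. Whatever is left on either side is unique.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._util import revcomp
from .simulate import PlatformDesign


class SequenceIndex:
    """Exact k-mer lookup over a set of sequences, both strands.

    Only forward k-mers are stored; a reverse-strand hit is found by
    querying the reverse complement of the probe. Per-length k-mer tables
    are built lazily on first query of that length.
    """

    def __init__(self, sequences: dict):
        if not sequences:
            raise ValueError("sequence set must be nonempty")
        self._seqs = dict(sequences)
        self._tables: dict = {}

    def _table(self, k: int) -> dict:
        tab = self._tables.get(k)
        if tab is None:
            tab = {}
            for sid, seq in self._seqs.items():
                for i in range(len(seq) - k + 1):
                    tab.setdefault(seq[i : i + k], set()).add(sid)
            self._tables[k] = tab
        return tab

    def find(self, probe: str) -> set:
        """All (sequence id, strand) pairs containing `probe` exactly.

        strand "forward" means the probe occurs verbatim in the sequence;
        "reverse" means its reverse complement does. A palindromic probe can
        hit the same sequence on both strands.
        """
        tab = self._table(len(probe))
        hits = {(sid, "forward") for sid in tab.get(probe, ())}
        hits |= {(sid, "reverse") for sid in tab.get(revcomp(probe), ())}
        return hits


@dataclass
class MatchResult:
    """Best single-sequence match of a probeset against an index."""

    probeset_id: str
    best_target_id: str | None
    n_probes_matched_to_best: int
    strand_of_best: str | None
    #: per-target probe-occurrence counts (all candidates, not just best)
    counts: dict = field(default_factory=dict)


@dataclass
class ContentPartition:
    """Per-platform common/unique split with per-probeset match details.

    ``classes`` maps platform label -> {"common": set, "unique": set,
    "excluded": set}; excluded probesets had no full-length sequence record
    and are reported rather than silently dropped. ``details`` maps
    probeset id -> MatchResult for probesets that were matched.
    """

    classes: dict
    details: dict = field(default_factory=dict)

    def summary(self) -> dict:
        out = {}
        for platform, cls in self.classes.items():
            out[platform] = {
                "total": len(cls["common"]) + len(cls["unique"]),
                "common": len(cls["common"]),
                "unique": len(cls["unique"]),
                "excluded": len(cls["excluded"]),
            }
        return out


def match_probeset(probeset, index: SequenceIndex) -> MatchResult:
    """Count, per candidate target, how many probes occur exactly in it.

    Each probe contributes at most 1 to each target it occurs in (on either
    strand). The best target is the one with the maximal count; ties break
    to the lexicographically smallest target id. The reported strand is the
    majority strand of the winning target's probe hits (forward on a tie).
    """
    counts: dict = {}
    strand_votes: dict = {}
    for probe in probeset.probes:
        seen = set()
        for sid, strand in index.find(probe):
            if sid not in seen:
                counts[sid] = counts.get(sid, 0) + 1
                seen.add(sid)
            strand_votes.setdefault(sid, {"forward": 0, "reverse": 0})
            strand_votes[sid][strand] += 1
    if not counts:
        return MatchResult(probeset.probeset_id, None, 0, None)
    best = min(counts, key=lambda sid: (-counts[sid], sid))
    votes = strand_votes[best]
    strand = "forward" if votes["forward"] >= votes["reverse"] else "reverse"
    return MatchResult(probeset.probeset_id, best, counts[best], strand, counts)


def _match_platform(platform: PlatformDesign, sequences: dict, min_probes: int):
    """Match every probeset of `platform` against `sequences`.

    Returns (details, qualifying) where qualifying maps probeset id -> set
    of target sequence ids reaching the >= min_probes rule.
    """
    index = SequenceIndex(sequences)
    details = {}
    qualifying = {}
    for pid in sorted(platform.probesets):
        mr = match_probeset(platform.probesets[pid], index)
        details[pid] = mr
        hits = {sid for sid, c in mr.counts.items() if c >= min_probes}
        if hits:
            qualifying[pid] = hits
    return details, qualifying


def classify_common_unique(
    platform_a: PlatformDesign,
    platform_b: PlatformDesign,
    min_probes: int = 6,
) -> ContentPartition:
    """Bidirectional common/unique partition of two platforms' probesets.

    Pass 1 matches platform B probesets against platform A full-length
    sequences; a probeset reaching ``min_probes`` exact full-length probe
    hits within one sequence marks itself and all platform-A probesets of
    that sequence common. Pass 2 matches platform A probesets against the
    full-length sequences of the platform-B probesets not yet common, with
    the symmetric marking. Probesets whose transcript has no sequence
    record are excluded and reported. Probesets with fewer than
    ``min_probes`` probes can never be common.
    """
    classes = {
        platform_a.name: {"common": set(), "unique": set(), "excluded": set()},
        platform_b.name: {"common": set(), "unique": set(), "excluded": set()},
    }
    details: dict = {}

    for platform in (platform_a, platform_b):
        for pid, ps in platform.probesets.items():
            if ps.transcript_id not in platform.transcripts:
                classes[platform.name]["excluded"].add(pid)

    a_by_seq = platform_a.probesets_by_transcript()
    b_by_seq = platform_b.probesets_by_transcript()
    a_common = classes[platform_a.name]["common"]
    b_common = classes[platform_b.name]["common"]
    a_excl = classes[platform_a.name]["excluded"]
    b_excl = classes[platform_b.name]["excluded"]

    # pass 1: B probesets vs A full sequences
    det1, qual1 = _match_platform(platform_b, platform_a.sequences, min_probes)
    details.update(det1)
    for pid, targets in qual1.items():
        if pid in b_excl:
            continue
        b_common.add(pid)
        for sid in targets:
            a_common.update(a_by_seq.get(sid, ()))

    # pass 2: A probesets vs full sequences of B probesets not yet common
    remaining_b = {
        pid for pid in platform_b.probesets if pid not in b_common and pid not in b_excl
    }
    remaining_seqs = {
        tid: platform_b.transcripts[tid].sequence
        for pid in remaining_b
        for tid in [platform_b.probesets[pid].transcript_id]
        if tid in platform_b.transcripts
    }
    if remaining_seqs:
        det2, qual2 = _match_platform(platform_a, remaining_seqs, min_probes)
        for pid, mr in det2.items():
            details.setdefault(pid, mr)
        for pid, targets in qual2.items():
            if pid in a_excl:
                continue
            a_common.add(pid)
            for sid in targets:
                b_common.update(b_by_seq.get(sid, ()) - b_excl)

    for platform in (platform_a, platform_b):
        cls = classes[platform.name]
        cls["unique"] = set(platform.probesets) - cls["common"] - cls["excluded"]
    return ContentPartition(classes, details)


def partition_frame(partition: ContentPartition) -> "pd.DataFrame":
    """Long-format table (probeset_id, platform, class, best_target, n_matched, strand)."""
    import pandas as pd

    rows = []
    for platform, cls in partition.classes.items():
        for label in ("common", "unique", "excluded"):
            for pid in sorted(cls[label]):
                mr = partition.details.get(pid)
                rows.append(
                    {
                        "probeset_id": pid,
                        "platform": platform,
                        "class": label,
                        "best_target": mr.best_target_id if mr else "",
                        "n_matched": mr.n_probes_matched_to_best if mr else 0,
                        "strand": mr.strand_of_best or "" if mr else "",
                    }
                )
    return pd.DataFrame(
        rows, columns=["probeset_id", "platform", "class", "best_target", "n_matched", "strand"]
    )
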