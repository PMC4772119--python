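"""Detection and refinement of single-span transmembrane domains.

The method runs in four deterministic steps per protein:

1. **rough scan** — slide an 18-residue window along the sequence and keep
   the window with the highest summed hydropathy, regardless of how many
   hydrophilic residues it contains (ties break to the smallest start).
2. **flank attachment** — extend the window by up to 8 residues on each
   side (truncated at the sequence ends), giving a candidate region of
   18-34 residues.
3. **edge refinement** — EXPAND each core edge outward through residues
   that are hydrophobic, or uncharged-hydrophilic and buried between >=3
   contiguous hydrophobic residues on both sides; then CONTRACT each edge
   by chopping terminal residues that are hydrophilic and not buried.
   Charged residues (D, E, K, R, H by default) are never buried-eligible.
   Interior hydrophilic residues are retained.
4. **orientation** — list the refined span from its cytosolic end
   (position 1) toward the exoplasmic end, using the topology annotation.

All coordinates are 1-based and inclusive.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .config import DEFAULT_CHARGED, RunConfig
from .hydropathy import HydropathyScale, get_scale
from .seqio import ProteinRecord, Topology

NO_TMD_FLAG = "no_tmd"
NO_TOPOLOGY_FLAG = "no_topology"


@dataclasses.dataclass
class TmdSpan:
    """A refined TM segment with its originating core window and flanks."""

    start: int
    end: int
    core_start: int
    core_end: int
    flank_left: int
    flank_right: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def candidate_start(self) -> int:
        return self.core_start - self.flank_left

    @property
    def candidate_end(self) -> int:
        return self.core_end + self.flank_right


@dataclasses.dataclass
class TmdRecord:
    """A detected, refined, cytosolically anchored TMD of one protein.

    ``oriented_sequence`` lists the refined residues from the cytosolic end
    (position 1) to the exoplasmic end. ``span`` is in original sequence
    coordinates. A record with the ``no_tmd`` flag has an empty span and is
    excluded from downstream statistics.
    """

    id: str
    span: TmdSpan | None
    sequence: str
    topology: Topology
    oriented_sequence: str
    scale: str
    group: str = ""
    flags: tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return len(self.oriented_sequence)

    @property
    def has_tmd(self) -> bool:
        return NO_TMD_FLAG not in self.flags and self.span is not None

    def oriented_residues(self, extent: int) -> str:
        """Residues from position 1 (cytosolic end of the span) outward.

        Positions beyond the refined span continue into the exoplasmic side
        of the full sequence, so aligned profiles can follow the
        hydrophobic-to-hydrophilic transition past the span end. Truncates
        at the end of the available sequence.
        """
        if self.span is None:
            return ""
        if self.topology is Topology.N_CYTO:
            start = self.span.start - 1
            return self.sequence[start : start + extent]
        if self.topology is Topology.C_CYTO:
            end = self.span.end  # exclusive slice bound
            return self.sequence[max(0, end - extent) : end][::-1]
        raise ValueError(f"record {self.id!r}: topology is UNKNOWN, cannot orient")


def rough_scan(
    sequence: str, scale: HydropathyScale, window: int = 18
) -> tuple[int, int]:
    """Return the (start, end) of the most hydrophobic window, 1-based.

    The winning window maximizes the summed hydropathy score; ties break
    to the smallest start index.
    """
    if len(sequence) < window:
        raise ValueError(
            f"sequence length {len(sequence)} is shorter than window {window}"
        )
    scores = scale.scores(sequence)
    sums = np.lib.stride_tricks.sliding_window_view(scores, window).sum(axis=1)
    start = int(np.argmax(sums)) + 1  # argmax returns the first maximum
    return start, start + window - 1


def attach_flanks(
    core: tuple[int, int], sequence_length: int, max_flank: int = 8
) -> TmdSpan:
    """Extend the core window by up to ``max_flank`` residues per side."""
    core_start, core_end = core
    if not (1 <= core_start <= core_end <= sequence_length):
        raise ValueError(f"core {core} out of bounds for length {sequence_length}")
    flank_left = min(max_flank, core_start - 1)
    flank_right = min(max_flank, sequence_length - core_end)
    return TmdSpan(
        start=core_start - flank_left,
        end=core_end + flank_right,
        core_start=core_start,
        core_end=core_end,
        flank_left=flank_left,
        flank_right=flank_right,
    )


def _hydro_mask(sequence: str, scale: HydropathyScale) -> list[bool]:
    thr = scale.hydrophobic_threshold
    return [scale.values[c] > thr for c in sequence]


def _buried(
    pos: int,
    hydro: list[bool],
    charged: frozenset[str],
    sequence: str,
    lo: int,
    hi: int,
    run: int,
) -> bool:
    """Buried rule: an *uncharged* hydrophilic residue at 0-based ``pos`` is
    buried iff >= ``run`` contiguous hydrophobic residues sit immediately on
    both sides, entirely within the candidate region [lo, hi]."""
    if sequence[pos] in charged:
        return False
    if pos - run < lo - 1 or pos + run > hi - 1:
        return False
    left_ok = all(hydro[pos - k] for k in range(1, run + 1))
    right_ok = all(hydro[pos + k] for k in range(1, run + 1))
    return left_ok and right_ok


def refine_edges(
    candidate: TmdSpan,
    sequence: str,
    scale: HydropathyScale,
    burial_run: int = 3,
    charged_residues: str = DEFAULT_CHARGED,
    expand_before_contract: bool = True,
) -> TmdSpan | None:
    """Refine the candidate region's edges to the final TM span.

    Returns ``None`` when refinement empties the span (no hydrophobic
    residue in the candidate), which callers flag as "no TMD".
    """
    hydro = _hydro_mask(sequence, scale)
    charged = frozenset(charged_residues)
    lo, hi = candidate.candidate_start, candidate.candidate_end

    def admissible(pos0: int) -> bool:
        return hydro[pos0] or _buried(pos0, hydro, charged, sequence, lo, hi, burial_run)

    def expand(start: int, end: int) -> tuple[int, int]:
        while start > lo and admissible(start - 1 - 1):
            start -= 1
        while end < hi and admissible(end + 1 - 1):
            end += 1
        return start, end

    def contract(start: int, end: int) -> tuple[int, int]:
        while start <= end and not admissible(start - 1):
            start += 1
        while end >= start and not admissible(end - 1):
            end -= 1
        return start, end

    start, end = candidate.core_start, candidate.core_end
    if expand_before_contract:
        start, end = expand(start, end)
        start, end = contract(start, end)
    else:
        start, end = contract(start, end)
        if start <= end:
            start, end = expand(start, end)
            start, end = contract(start, end)
    if start > end:
        return None
    return TmdSpan(
        start=start,
        end=end,
        core_start=candidate.core_start,
        core_end=candidate.core_end,
        flank_left=candidate.flank_left,
        flank_right=candidate.flank_right,
    )


def orient(
    span: TmdSpan,
    sequence: str,
    topology: Topology,
    record_id: str = "",
    scale_name: str = "GES",
    group: str = "",
) -> TmdRecord:
    """Anchor the refined span at its cytosolic end (position 1).

    N-cytosolic proteins keep sequence order; C-cytosolic proteins are
    reversed so position 1 is always the cytosolic-most refined residue.
    """
    residues = sequence[span.start - 1 : span.end]
    if topology is Topology.N_CYTO:
        oriented = residues
    elif topology is Topology.C_CYTO:
        oriented = residues[::-1]
    else:
        raise ValueError(
            f"record {record_id!r}: topology must be N_CYTO or C_CYTO to orient "
            f"(got UNKNOWN)"
        )
    return TmdRecord(
        id=record_id,
        span=span,
        sequence=sequence,
        topology=topology,
        oriented_sequence=oriented,
        scale=scale_name,
        group=group,
    )


def detect(
    record: ProteinRecord,
    scale: HydropathyScale | None = None,
    config: RunConfig | None = None,
    lenient_topology: bool = False,
) -> TmdRecord:
    """Full per-protein detection: scan -> flanks -> refine -> orient."""
    config = config or RunConfig()
    scale = scale or get_scale(config.scale, config.hydrophobic_threshold)
    core = rough_scan(record.sequence, scale, config.window)
    candidate = attach_flanks(core, len(record.sequence), config.max_flank)
    span = refine_edges(
        candidate,
        record.sequence,
        scale,
        burial_run=config.burial_run,
        charged_residues=config.charged_residues,
        expand_before_contract=config.expand_before_contract,
    )
    if span is None:
        return TmdRecord(
            id=record.id,
            span=None,
            sequence=record.sequence,
            topology=record.topology,
            oriented_sequence="",
            scale=scale.name,
            group=record.group,
            flags=(NO_TMD_FLAG,),
        )
    if record.topology is Topology.UNKNOWN:
        if not lenient_topology:
            raise ValueError(
                f"record {record.id!r}: topology is UNKNOWN; annotate N_CYTO or "
                f"C_CYTO, or run with lenient_topology"
            )
        return TmdRecord(
            id=record.id,
            span=span,
            sequence=record.sequence,
            topology=record.topology,
            oriented_sequence="",
            scale=scale.name,
            group=record.group,
            flags=(NO_TOPOLOGY_FLAG,),
        )
    out = orient(span, record.sequence, record.topology, record.id, scale.name, record.group)
    return out


def candidate_subsequence(record: ProteinRecord, tmd: TmdRecord) -> str:
    """The TMD+flank (candidate-region) subsequence used for clustering."""
    if tmd.span is None:
        return ""
    return record.sequence[tmd.span.candidate_start - 1 : tmd.span.candidate_end]


# ---------------------------------------------------------------------------
# TMD table I/O

TMD_TABLE_COLUMNS = [
    "id",
    "group",
    "start",
    "end",
    "length",
    "oriented_sequence",
    "scale",
    "flags",
]


def write_tmd_table(records: list[TmdRecord], path) -> None:
    import pandas as pd

    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "group": r.group,
                "start": r.span.start if r.span else 0,
                "end": r.span.end if r.span else 0,
                "length": r.length,
                "oriented_sequence": r.oriented_sequence,
                "scale": r.scale,
                "flags": ";".join(r.flags),
            }
        )
    pd.DataFrame(rows, columns=TMD_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_tmd_table(path):
    """Read a TMD table TSV back into a DataFrame (ids/flags as strings)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"id": str, "group": str, "flags": str})
    df["flags"] = df["flags"].fillna("")
    df["group"] = df["group"].fillna("")
    missing = [c for c in TMD_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing TMD table column(s) {missing}")
    return df
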