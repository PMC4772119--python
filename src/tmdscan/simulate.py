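"""Synthetic sequences with planted TMDs for end-to-end testing.

The generator plants a single hydrophobic run of known extent between
hydrophilic flanks, so the detection pipeline can be scored against exact
ground truth without any database downloads. Helices longer than the scan
window are given a hydrophobicity taper — the strongest-scoring residues
in a window-sized central core, weaker hydrophobic residues toward the
helix ends — mirroring the bilayer-core/interface gradient of natural TM
helices and making the most-hydrophobic window sit at the helix center.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .hydropathy import HydropathyScale, get_scale
from .seqio import ProteinRecord, Topology

#: Default residue pools. All hydrophobic-pool residues score > 0 and all
#: hydrophilic-pool residues score < 0 on both bundled scales (serine is
#: excluded from the hydrophilic pool because GES scores it +0.6).
HYDROPHOBIC_POOL = "LIVFMA"
HYDROPHILIC_POOL = "DEKRNQ"

MIN_TMD, MAX_TMD = 5, 40


@dataclasses.dataclass
class PlantedTruth:
    """Ground truth of one planted TMD (1-based inclusive coordinates)."""

    id: str
    true_start: int
    true_end: int
    true_length: int
    topology: Topology
    group: str


def _validate_alphabets(
    hydrophobic: str, hydrophilic: str, scale: HydropathyScale
) -> None:
    overlap = set(hydrophobic) & set(hydrophilic)
    if overlap:
        raise ValueError(f"alphabets overlap: {sorted(overlap)}")
    wrong_phobic = [c for c in hydrophobic if not scale.is_hydrophobic(c)]
    wrong_philic = [c for c in hydrophilic if scale.is_hydrophobic(c)]
    if wrong_phobic or wrong_philic:
        raise ValueError(
            f"alphabets inconsistent with scale {scale.name}: "
            f"non-hydrophobic in hydrophobic pool {wrong_phobic}, "
            f"hydrophobic in hydrophilic pool {wrong_philic}"
        )


def _tapered_run(
    length: int,
    rng: np.random.Generator,
    alphabet: str,
    scale: HydropathyScale,
    window: int,
) -> str:
    """A hydrophobic run; runs longer than the window get a central core
    drawn from the stronger half of the alphabet and periphery from the
    weaker half, so the maximal window is unambiguous and centered."""
    letters = sorted(alphabet, key=scale.score)
    if length <= window:
        return "".join(rng.choice(list(alphabet), size=length))
    weak, strong = letters[: len(letters) // 2], letters[len(letters) // 2 :]
    if scale.score(min(strong, key=scale.score)) <= scale.score(
        max(weak, key=scale.score)
    ):
        raise ValueError(
            f"hydrophobic alphabet {alphabet!r} cannot be split into strictly "
            f"separated core/periphery pools under scale {scale.name}"
        )
    core_start = (length - window) // 2  # 0-based offset of the core
    out = []
    for i in range(length):
        pool = strong if core_start <= i < core_start + window else weak
        out.append(rng.choice(pool))
    return "".join(out)


def plant_tmd(
    length: int,
    flank_hydrophilic_len: int,
    seed: int | np.random.Generator,
    hydrophobic_alphabet: str = HYDROPHOBIC_POOL,
    hydrophilic_alphabet: str = HYDROPHILIC_POOL,
    scale: HydropathyScale | None = None,
    window: int = 18,
    record_id: str = "planted",
    group: str = "synthetic",
    topology: Topology = Topology.N_CYTO,
) -> tuple[str, PlantedTruth]:
    """Build one sequence: hydrophilic flank + hydrophobic run + flank.

    The planted run is the unique maximal run of hydrophobic residues in
    the sequence. Deterministic for a given seed.
    """
    if not (MIN_TMD <= length <= MAX_TMD):
        raise ValueError(f"length must be in [{MIN_TMD}, {MAX_TMD}], got {length}")
    if flank_hydrophilic_len < (window + 1) // 2:
        raise ValueError(
            f"flank length must be >= window/2 = {(window + 1) // 2}, "
            f"got {flank_hydrophilic_len}"
        )
    scale = scale or get_scale("GES")
    _validate_alphabets(hydrophobic_alphabet, hydrophilic_alphabet, scale)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    philic = list(hydrophilic_alphabet)
    left = "".join(rng.choice(philic, size=flank_hydrophilic_len))
    right = "".join(rng.choice(philic, size=flank_hydrophilic_len))
    run = _tapered_run(length, rng, hydrophobic_alphabet, scale, window)
    sequence = left + run + right
    truth = PlantedTruth(
        id=record_id,
        true_start=flank_hydrophilic_len + 1,
        true_end=flank_hydrophilic_len + length,
        true_length=length,
        topology=topology,
        group=group,
    )
    return sequence, truth


def generate_group(
    n: int,
    length_mean: float,
    length_sd: float,
    seed: int,
    group: str = "synthetic",
    flank_len: int = 12,
    **plant_kwargs,
) -> tuple[list[ProteinRecord], list[PlantedTruth]]:
    """Generate ``n`` annotated records with rounded-normal TMD lengths.

    Lengths are drawn from N(length_mean, length_sd), rounded and clipped
    to [8, 34]; topologies alternate deterministically between N_CYTO and
    C_CYTO draws.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if length_sd < 0:
        raise ValueError(f"length_sd must be >= 0, got {length_sd}")
    rng = np.random.default_rng(seed)
    lengths = np.clip(
        np.rint(rng.normal(length_mean, length_sd, size=n)).astype(int), 8, 34
    )
    records, truths = [], []
    for i, length in enumerate(lengths):
        topo = Topology.N_CYTO if rng.random() < 0.5 else Topology.C_CYTO
        rid = f"{group}_{i:04d}"
        seq, truth = plant_tmd(
            int(length),
            flank_len,
            rng,
            record_id=rid,
            group=group,
            topology=topo,
            **plant_kwargs,
        )
        records.append(ProteinRecord(id=rid, sequence=seq, group=group, topology=topo))
        truths.append(truth)
    return records, truths


def edge_case_suite() -> list[tuple[ProteinRecord, int, str]]:
    """Hand-built sequences exercising each edge-refinement rule.

    Returns (record, expected refined length, description) triples. Every
    sequence carries strongly charged flanks so the rough window is pinned
    to the planted region.
    """
    pad = "DEKR" * 3  # 12 strongly hydrophilic, charged residues
    cases = [
        # interior hydrophilic residue is retained
        ("LLLLLLLLDLLLLLLLLL", 18, "mid-core charged D retained (interior rule)"),
        ("LLLLLLLLNLLLLLLLLL", 18, "mid-core uncharged N retained (interior rule)"),
        # hydrophilic residues at the edge without burial are chopped
        ("LLLLLLLLLLLLLLLLDD", 16, "edge DD chopped (contract rule)"),
        ("NNLLLLLLLLLLLLLLLL", 16, "edge NN chopped even though uncharged"),
        # buried uncharged hydrophilic at the expansion boundary is retained
        ("LLLNLLLLLLLLLLLLLLLLLL", 22, "N buried by 3+3 hydrophobic, retained"),
        # charged residue in the same context is never buried-eligible
        ("LLLDLLLLLLLLLLLLLLLLLL", 18, "charged D blocks expansion past it"),
        # hydrophobic flank residues are annexed by expansion
        ("LLLLLLLLLLLLLLLLLLLLL", 21, "hydrophobic flank annexed (expand rule)"),
    ]
    out = []
    for i, (tm, expected, why) in enumerate(cases):
        seq = pad + tm + pad
        rec = ProteinRecord(
            id=f"edge_{i}", sequence=seq, group="edge", topology=Topology.N_CYTO
        )
        out.append((rec, expected, why))
    # TMD at the very start of the sequence: left flank truncates to zero
    out.append(
        (
            ProteinRecord(
                id="edge_terminus",
                sequence="L" * 18 + pad,
                group="edge",
                topology=Topology.N_CYTO,
            ),
            18,
            "TMD at sequence terminus; left flank truncated to 0",
        )
    )
    return out
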