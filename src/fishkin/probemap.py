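"""Probe-library model on a transcript and the nascent-signal weighting factor.

An smFISH probe library tiles a transcript with short (~20 nt) antisense
oligos. A mature mRNA carries every probe site; a *nascent* transcript only
carries the sites 5' of the polymerase. The weighting factor K is the
expected fraction of the library hybridisable on a nascent transcript whose
polymerase sits uniformly along the gene — it converts the integrated
intensity of a transcription focus (measured in units of one mature
transcript) into a number of engaged polymerases.

Coordinates are transcript-space, 1-based, closed intervals: probe position
x_i is the nucleotide coordinate of the probe's centre on the mature
transcript of length L.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq
from Bio import SeqIO

__all__ = [
    "TranscriptModel",
    "ProbeMappingResult",
    "map_probes",
    "weighting_factor",
    "nascent_signal_fraction",
    "read_probe_positions_csv",
    "read_probe_sequences",
    "read_transcript_fasta",
]


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript with a mapped smFISH probe library.

    Parameters
    ----------
    gene_id : str
        Gene/transcript identifier.
    length_nt : int
        Length L of the mature transcript in nucleotides.
    probe_positions : tuple of int
        1-based coordinate of each probe's centre, sorted ascending.
    probe_length_nt : int
        Probe footprint length (default 20 nt).
    chromosome_copies : int
        Number of scorable alleles c (1 for an X-linked gene in males).
    name : str
        Human-readable name.
    """

    gene_id: str
    length_nt: int
    probe_positions: tuple[int, ...]
    probe_length_nt: int = 20
    chromosome_copies: int = 1
    name: str = ""

    def __post_init__(self) -> None:
        if self.length_nt <= 0:
            raise ValueError("transcript length must be positive")
        if len(self.probe_positions) == 0:
            raise ValueError("probe_positions must be non-empty")
        pos = tuple(int(p) for p in self.probe_positions)
        if any(p < 1 or p > self.length_nt for p in pos):
            raise ValueError("probe positions must satisfy 1 <= x_i <= L")
        object.__setattr__(self, "probe_positions", tuple(sorted(pos)))
        if self.probe_length_nt <= 0:
            raise ValueError("probe length must be positive")
        if self.chromosome_copies < 1:
            raise ValueError("chromosome_copies must be >= 1")

    @property
    def n_probes(self) -> int:
        return len(self.probe_positions)


@dataclass
class ProbeMappingResult:
    """Outcome of mapping probe sequences onto a transcript."""

    model: TranscriptModel
    unmatched: list[str] = field(default_factory=list)
    ambiguous: list[str] = field(default_factory=list)


def map_probes(
    probe_sequences: Sequence[str],
    transcript_sequence: str,
    gene_id: str = "gene",
    chromosome_copies: int = 1,
    name: str = "",
) -> ProbeMappingResult:
    """Locate probes on a transcript by exact match and build a model.

    Probes are antisense by construction, so each probe is searched as the
    reverse complement against the transcript (and, for convenience, in the
    sense orientation as well; a probe matching both strands resolves to the
    antisense match). The recorded coordinate is the centre of the matched
    footprint, 1-based. Probes with zero or more than one match are reported
    separately and excluded from the model.

    Raises
    ------
    ValueError
        If the transcript is empty, a probe length is outside 15-30 nt, or
        no probe matches at all.
    """
    transcript = transcript_sequence.strip().upper().replace("U", "T")
    if not transcript:
        raise ValueError("transcript sequence is empty")

    positions: list[int] = []
    unmatched: list[str] = []
    ambiguous: list[str] = []
    for raw in probe_sequences:
        probe = raw.strip().upper().replace("U", "T")
        if not 15 <= len(probe) <= 30:
            raise ValueError(
                f"probe length {len(probe)} nt outside the 15-30 nt smFISH range"
            )
        antisense_target = str(Seq(probe).reverse_complement())
        hits = _find_all(transcript, antisense_target)
        if not hits:
            # fall back to a sense-orientation match (probe given as the
            # transcript-strand sequence rather than the oligo itself)
            hits = _find_all(transcript, probe)
        if len(hits) == 0:
            unmatched.append(raw)
        elif len(hits) > 1:
            ambiguous.append(raw)
        else:
            start = hits[0]  # 0-based
            centre = start + (len(probe) + 1) // 2  # 1-based centre
            positions.append(centre)

    if not positions:
        raise ValueError("probe set does not match transcript")

    model = TranscriptModel(
        gene_id=gene_id,
        length_nt=len(transcript),
        probe_positions=tuple(sorted(positions)),
        probe_length_nt=len(probe_sequences[0].strip()),
        chromosome_copies=chromosome_copies,
        name=name,
    )
    return ProbeMappingResult(model=model, unmatched=unmatched, ambiguous=ambiguous)


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1


def weighting_factor(model: TranscriptModel) -> float:
    """Expected hybridisable fraction K of the probe library.

    For a polymerase position uniform on [0, L] a probe centred at x_i is
    synthesised with probability (L - x_i)/L, so

        K = (1/n) * sum_i (L - x_i) / L,    0 < K <= 1.

    Libraries near the 5' end give K -> 1; libraries at the 3' end give
    small K (most nascent transcripts carry no probe sites yet).
    """
    L = model.length_nt
    k = sum((L - x) / L for x in model.probe_positions) / model.n_probes
    if not 0.0 < k <= 1.0:
        raise ValueError(f"weighting factor {k} outside (0, 1]")
    return k


def nascent_signal_fraction(polymerase_position: float, model: TranscriptModel) -> float:
    """Fraction of probe sites already synthesised at a polymerase position.

    A probe site counts fully once the polymerase has passed its centre
    (step function, no partial sites). Returns (1/n) * #{i : position >= x_i}.
    """
    if not 0 <= polymerase_position <= model.length_nt:
        raise ValueError(
            f"polymerase position {polymerase_position} outside [0, {model.length_nt}]"
        )
    n_passed = sum(1 for x in model.probe_positions if polymerase_position >= x)
    return n_passed / model.n_probes


# ---------------------------------------------------------------------------
# I/O

def read_probe_positions_csv(path: str | Path) -> list[int]:
    """Read probe centre positions from a CSV with columns probe_id, position_nt."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "position_nt" not in reader.fieldnames:
            raise ValueError("probe CSV must have a 'position_nt' column")
        return [int(row["position_nt"]) for row in reader]


def read_probe_sequences(path: str | Path) -> list[str]:
    """Read probe sequences from FASTA or plain text (one sequence per line)."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith(">"):
        return [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    return [line.strip() for line in text.splitlines() if line.strip()]


def read_transcript_fasta(path: str | Path) -> str:
    """Read the (single) transcript sequence from a FASTA file."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return str(records[0].seq)
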