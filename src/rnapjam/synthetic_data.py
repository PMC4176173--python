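"""Synthetic sequencing data with known ground truth.

Generates a random reference, then 135-nt reads drawn uniformly from both
strands with three independent per-base substitution-error channels applied
in the order the molecules acquire them — transcription, reverse
transcription, sequencing — plus per-base phred qualities.  A manifest
records every read's true origin and every injected error, so downstream
mismatch-rate estimates can be checked against exact truth.

All randomness comes from one seeded generator drawing fixed-shape arrays,
so two error models with the same seed are coupled: raising one channel's
rate yields a superset of that channel's errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ErrorModel",
    "default_quality_profile",
    "generate_reference",
    "generate_reads",
    "combined_error_probability",
    "make_scenario_suite",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {**{a: b for a, b in zip("ACGTN", "TGCAN")}}

#: Default read length; trimming 20 nt from each end leaves the 95-nt core.
DEFAULT_READ_LEN = 135


def default_quality_profile(read_len: int = DEFAULT_READ_LEN) -> np.ndarray:
    """Phred 38 plateau with a mild 3' decay to 30 over the last quarter."""
    prof = np.full(read_len, 38.0)
    tail = max(1, read_len // 4)
    prof[-tail:] = np.linspace(38.0, 30.0, tail)
    return prof


@dataclass(frozen=True)
class ErrorModel:
    """Per-base substitution probabilities of the three error channels.

    ``e_tx``: transcription errors (the biological signal of interest);
    ``e_rt``: reverse-transcription errors (library construction);
    ``e_seq``: sequencer errors.  ``low_q_rate`` injects occasional
    low-quality calls (phred 10) to exercise the quality filter.
    """

    e_tx: float = 0.0
    e_rt: float = 0.0
    e_seq: float = 0.0
    quality_profile: np.ndarray = field(default_factory=default_quality_profile)
    low_q_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("e_tx", "e_rt", "e_seq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.1:
                raise ValueError(f"{name}={v} outside [0, 0.1]")
        object.__setattr__(
            self, "quality_profile", np.asarray(self.quality_profile, dtype=float)
        )


def combined_error_probability(model: ErrorModel) -> float:
    """Probability that at least one channel hits a base:
    ``1 - (1-e_tx)(1-e_rt)(1-e_seq)``."""
    return 1.0 - (1 - model.e_tx) * (1 - model.e_rt) * (1 - model.e_seq)


def generate_reference(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """Seeded random DNA sequence with expected GC content ``gc``."""
    if length < 1000:
        raise ValueError("reference length must be >= 1000")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    codes = rng.choice(4, size=length, p=p)
    return _BASES[codes].tobytes().decode()


def _revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def generate_reads(
    reference: str,
    n: int,
    read_len: int = DEFAULT_READ_LEN,
    model: ErrorModel | None = None,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Simulate ``n`` reads; returns (FASTQ records, ground-truth manifest).

    Origins are uniform over both strands.  Each channel substitutes hit
    bases with a uniformly chosen different base, sequentially in channel
    order.  The manifest lists, per read: 1-based reference start of the
    origin window, strand, the 1-based read positions hit by each channel,
    and the net mismatch count versus the error-free read.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    L = len(reference)
    if read_len > L:
        raise ValueError("read_len exceeds reference length")
    model = model or ErrorModel()
    if model.quality_profile.size < read_len:
        raise ValueError("quality profile shorter than read length")
    rng = np.random.default_rng(model.seed)

    ref_codes = np.frombuffer(reference.encode(), dtype=np.uint8)
    lut = np.zeros(256, np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    ref_num = lut[ref_codes]  # 0..3

    starts = rng.integers(0, L - read_len + 1, size=n)
    strands = rng.integers(0, 2, size=n)  # 0 plus, 1 minus

    idx = starts[:, None] + np.arange(read_len)[None, :]
    reads = ref_num[idx]
    minus = strands == 1
    reads[minus] = (3 - reads[minus])[:, ::-1]  # reverse complement

    truth = reads.copy()
    hits = {}
    for channel, rate in (("tx", model.e_tx), ("rt", model.e_rt), ("seq", model.e_seq)):
        u = rng.random((n, read_len))
        shift = rng.integers(1, 4, size=(n, read_len))
        mask = u < rate
        reads = np.where(mask, (reads + shift) % 4, reads)
        hits[channel] = mask

    jitter = rng.integers(-2, 3, size=(n, read_len))
    lowq = rng.random((n, read_len)) < model.low_q_rate
    quals = np.clip(
        np.rint(model.quality_profile[:read_len][None, :] + jitter), 2, 41
    ).astype(int)
    quals = np.where(lowq, 10, quals)

    records, rows = [], []
    n_mm = (reads != truth).sum(axis=1)
    for i in range(n):
        rid = f"read_{i:06d}"
        seq = _BASES[reads[i]].tobytes().decode()
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = quals[i].tolist()
        records.append(rec)
        rows.append(
            (
                rid,
                int(starts[i]) + 1,
                "-" if strands[i] else "+",
                ",".join(str(p + 1) for p in np.nonzero(hits["tx"][i])[0]),
                ",".join(str(p + 1) for p in np.nonzero(hits["rt"][i])[0]),
                ",".join(str(p + 1) for p in np.nonzero(hits["seq"][i])[0]),
                int(n_mm[i]),
            )
        )
    manifest = pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "origin_start",
            "strand",
            "tx_errors",
            "rt_errors",
            "seq_errors",
            "n_mismatches",
        ],
    )
    return records, manifest


def write_fasta(sequence: str, path, name: str = "synthetic_ref") -> None:
    SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")], str(path), "fasta")


def write_fastq(records, path) -> None:
    SeqIO.write(records, str(path), "fastq")


def make_scenario_suite(outdir, seed: int = 0) -> list[Path]:
    """Write the documented default configs for every preset experiment.

    Emits one YAML per kinetic scenario (wild type + the three no-Gre
    hypotheses) and one per fidelity condition (2 genotypes x 2 reverse
    transcriptases), each with fixed seeds so regeneration is
    byte-identical.
    """
    import yaml

    from . import presets
    from .core_model import SCENARIO_NAMES

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    gene = presets.default_gene()
    for name in SCENARIO_NAMES:
        base, scen = presets.kinetic_preset(name)
        cfg = {
            "experiment": "induction",
            "gene": gene.to_dict(),
            "kinetics": scen.to_dict(),
            "baseline_kinetics": base.to_dict(),
            "scenario": {
                "name": name,
                "factor": presets.SCENARIO_FACTORS.get(name, 1.0),
            },
            "n_runs": 1000,
            "duration": presets.INDUCTION_DURATION,
            "record_interval": presets.INDUCTION_RECORD_INTERVAL,
            "seed": seed,
        }
        p = outdir / f"kinetic_{name}.yaml"
        p.write_text(yaml.safe_dump(cfg, sort_keys=False))
        written.append(p)
    for name, rates in presets.FIDELITY_PRESETS.items():
        cfg = {
            "experiment": "fidelity-sim",
            "reference": {"length": 10000, "gc": 0.4, "seed": seed + 1},
            "reads": {"n": 4000, "read_len": DEFAULT_READ_LEN},
            "error_model": {**rates, "low_q_rate": 0.005, "seed": seed + 2},
            "label": name,
        }
        p = outdir / f"fidelity_{name}.yaml"
        p.write_text(yaml.safe_dump(cfg, sort_keys=False))
        written.append(p)
    return written
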