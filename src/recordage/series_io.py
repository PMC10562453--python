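"""Trajectory CSV round-trips, FASTA -> DNA walk conversion, and
deterministic toy-fixture generation.

The trajectory interchange format is a plain CSV with columns
``traj_id,t,x`` (times may be floating point, e.g. for scaled Brownian
motion); an optional JSON sidecar carries ensemble metadata.  A DNA walk
maps each nucleotide to a +/-1 step (A/T -> +1, C/G -> -1) so that genomic
composition correlations become the increments of a one-dimensional walk.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulators import Trajectory, simulate, simulate_fbm

__all__ = [
    "DnaWalk",
    "fasta_to_walk",
    "fasta_walks",
    "read_trajectories",
    "write_trajectories",
    "fixture_generator",
    "FIXTURE_NAMES",
]

_STEP = {"A": 1, "T": 1, "U": 1, "C": -1, "G": -1}


@dataclass
class DnaWalk:
    """A nucleotide sequence rendered as a +/-1 walk.

    Weak pairs (A/T) step up, strong pairs (C/G) step down; ambiguity codes
    are skipped and counted.  Sequence positions are 1-based in reports,
    walk time is 0-based.
    """

    sequence_id: str
    steps: np.ndarray
    positions: np.ndarray
    skipped: int

    def trajectory(self) -> Trajectory:
        x = np.concatenate([[0], self.positions])
        return Trajectory(np.arange(len(x), dtype=float), x)


def _seq_to_walk(seq_id: str, seq: str) -> DnaWalk:
    steps, skipped = [], 0
    for ch in seq.upper():
        s = _STEP.get(ch)
        if s is None:
            skipped += 1
        else:
            steps.append(s)
    if not steps:
        raise ValueError(f"sequence {seq_id!r} empty after skipping ambiguous symbols")
    steps = np.asarray(steps, dtype=np.int64)
    return DnaWalk(seq_id, steps, np.cumsum(steps), skipped)


def fasta_to_walk(record) -> DnaWalk:
    """Convert one Bio.SeqRecord (or a raw string) to a DNA walk."""
    if isinstance(record, str):
        return _seq_to_walk("<string>", record)
    return _seq_to_walk(record.id, str(record.seq))


def fasta_walks(path) -> list[DnaWalk]:
    """All records of a (multi-)FASTA file as independent DNA walks."""
    walks = [fasta_to_walk(rec) for rec in SeqIO.parse(str(path), "fasta")]
    if not walks:
        raise ValueError(f"no FASTA records found in {path}")
    return walks


# ---------------------------------------------------------------------------
# trajectory CSV
# ---------------------------------------------------------------------------

def write_trajectories(trajectories, path, metadata: dict | None = None) -> None:
    """Write an ensemble as CSV ``traj_id,t,x`` (lossless float round-trip)
    with an optional JSON metadata sidecar ``<path>.json``."""
    frames = []
    for i, tr in enumerate(trajectories):
        frames.append(
            pd.DataFrame({"traj_id": i, "t": tr.times, "x": np.asarray(tr.positions, dtype=float)})
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    if metadata is not None:
        Path(str(path) + ".json").write_text(json.dumps(metadata, indent=1, default=str))


def read_trajectories(path) -> list[Trajectory]:
    """Read a ``traj_id,t,x`` CSV; rows of each trajectory must be
    time-sorted and free of NaNs, else an error names the offending row."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"traj_id", "t", "x"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    bad = df.index[df[["t", "x"]].isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"{path}: NaN value at data row {int(bad[0])}")
    out = []
    for tid, g in df.groupby("traj_id", sort=True):
        t = g["t"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            row = g.index[np.flatnonzero(np.diff(t) < 0)[0] + 1]
            raise ValueError(f"{path}: unsorted time at data row {int(row)} (traj_id={tid})")
        out.append(Trajectory(t, g["x"].to_numpy(dtype=float)))
    return out


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("dna_longrange", "pareto_ages", "trajectory_bundle")


def _longrange_sequence(seed: int, length: int = 50_000, H: float = 0.67) -> SeqRecord:
    """Pseudo-random nucleotide sequence with long-range-correlated
    composition, built by taking the signs of fractional Gaussian noise of
    Hurst exponent H: sign-clipping preserves the correlation exponent, so
    the resulting DNA walk has walk dimension close to 1/H by construction.
    Synthetic stand-in for a genomic sequence; not biological data."""
    fbm = simulate_fbm(H, length, seed)
    fgn = np.diff(fbm.positions)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 997])))
    up = rng.random(length) < 0.5
    letters = np.where(fgn > 0, np.where(up, "A", "T"), np.where(up, "C", "G"))
    return SeqRecord(
        Seq("".join(letters)),
        id=f"synthetic_lrc_H{H:g}_seed{seed}",
        description="synthetic long-range-correlated composition (sign-clipped fractional noise)",
    )


def fixture_generator(name: str, seed: int, out_dir=None):
    """Deterministic toy datasets for docs, tests and CLI examples.

    * ``dna_longrange`` -- 50 kb synthetic FASTA whose DNA walk has a known
      target walk dimension (H = 0.67 construction);
    * ``pareto_ages`` -- i.i.d. Pareto(theta = 0.5) record ages with known
      closed-form survival, as a record-series CSV of synthetic T_n;
    * ``trajectory_bundle`` -- a small simple-walk ensemble CSV.

    With ``out_dir`` the fixture is also written to disk (same name + seed
    always reproduces byte-identical files); the in-memory object is
    returned either way.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 131])))
    if name == "dna_longrange":
        rec = _longrange_sequence(seed)
        if out_dir is not None:
            SeqIO.write([rec], str(Path(out_dir) / "dna_longrange.fasta"), "fasta")
        return rec
    if name == "pareto_ages":
        # 2000 series of 30 ages each: tau = (1-u)^(-1/theta), theta = 0.5
        theta = 0.5
        ages = (1.0 - rng.random((2000, 30))) ** (-1.0 / theta)
        if out_dir is not None:
            df = pd.DataFrame(
                {
                    "series_id": np.repeat(np.arange(ages.shape[0]), ages.shape[1]),
                    "age": ages.ravel(),
                }
            )
            df.to_csv(Path(out_dir) / "pareto_ages.csv", index=False)
        return ages
    if name == "trajectory_bundle":
        trajs = simulate("simple_rw", n_steps=512, n_traj=8, seed=seed)
        if out_dir is not None:
            write_trajectories(
                trajs,
                Path(out_dir) / "trajectory_bundle.csv",
                metadata={"model": "simple_rw", "n_steps": 512, "n_traj": 8, "seed": seed},
            )
        return trajs
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
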