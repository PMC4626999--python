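"""Recording and cohort containers plus plain-text (CSV) persistence.

A :class:`PPGRecording` is the unit of analysis: one 20-s single-channel
fingertip PPG trace with a subject identifier and a session condition --
``BE`` (before exercise, i.e. rest) or ``E1``/``E2``/``E3`` (the rest
period after each of three exercise bouts under heat stress). Synthetic
recordings additionally carry ground-truth systolic peak times.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Session conditions: rest baseline plus the three post-exercise stages.
CONDITIONS = ("BE", "E1", "E2", "E3")

#: Post-exercise (heat-stress) conditions only.
STRESS_CONDITIONS = ("E1", "E2", "E3")


@dataclass
class PPGRecording:
    """One PPG recording with its sampling rate and session labels.

    Parameters
    ----------
    samples : ndarray
        Amplitude vector in arbitrary units.
    fs : float
        Sampling frequency in Hz.
    subject_id : str
        Subject identifier, unique within a cohort.
    condition : str
        One of :data:`CONDITIONS`.
    true_peak_times : ndarray, optional
        Ground-truth systolic peak times in seconds (synthetic data only).
    filtered : bool
        Whether the samples have been band-passed.
    """

    samples: np.ndarray
    fs: float
    subject_id: str = "S000"
    condition: str = "BE"
    true_peak_times: np.ndarray | None = None
    filtered: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D vector")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.true_peak_times is not None:
            self.true_peak_times = np.asarray(self.true_peak_times, dtype=float)

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return len(self.samples) / self.fs

    @property
    def t(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(len(self.samples)) / self.fs

    def with_samples(self, samples: np.ndarray, *, filtered: bool | None = None) -> "PPGRecording":
        """Copy of this recording with new samples (labels preserved)."""
        return replace(
            self,
            samples=np.asarray(samples, dtype=float),
            filtered=self.filtered if filtered is None else filtered,
        )


@dataclass
class CohortDataset:
    """A set of recordings (one per subject x condition) plus its provenance.

    ``config`` is a plain dict snapshot of the generating parameters so a
    dataset read back from disk carries the same provenance as a freshly
    generated one.
    """

    recordings: list[PPGRecording] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [(r.subject_id, r.condition) for r in self.recordings]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (subject_id, condition) pairs in cohort")

    def __len__(self) -> int:
        return len(self.recordings)

    def __iter__(self):
        return iter(self.recordings)

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.recordings:
            seen.setdefault(r.subject_id, None)
        return list(seen)

    @property
    def conditions(self) -> list[str]:
        return [c for c in CONDITIONS if any(r.condition == c for r in self.recordings)]

    def get(self, subject_id: str, condition: str) -> PPGRecording:
        for r in self.recordings:
            if r.subject_id == subject_id and r.condition == condition:
                return r
        raise KeyError(f"no recording for subject {subject_id!r}, condition {condition!r}")

    def by_condition(self, condition: str) -> list[PPGRecording]:
        return [r for r in self.recordings if r.condition == condition]

    # ------------------------------------------------------------------ I/O

    def to_dir(self, outdir: str | Path) -> None:
        """Write one CSV per recording plus a cohort manifest.

        Each recording file has a ``# fs=<Hz>`` header comment and a single
        ``ppg`` column; the manifest lists subject, condition and file name.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = []
        for r in self.recordings:
            fname = f"{r.subject_id}_{r.condition}.csv"
            with open(outdir / fname, "w") as fh:
                fh.write(f"# fs={r.fs}\n")
                fh.write("ppg\n")
                np.savetxt(fh, r.samples, fmt="%.10g")
            rows.append({"subject_id": r.subject_id, "condition": r.condition, "file": fname})
        manifest = pd.DataFrame(rows)
        manifest["seed"] = self.config.get("seed", "")
        manifest.to_csv(outdir / "manifest.csv", index=False)
        with open(outdir / "config.json", "w") as fh:
            json.dump(self.config, fh, indent=2, default=str)

    @classmethod
    def from_dir(cls, indir: str | Path) -> "CohortDataset":
        """Read a cohort written by :meth:`to_dir`."""
        indir = Path(indir)
        manifest = pd.read_csv(indir / "manifest.csv")
        config: dict = {}
        cfg_path = indir / "config.json"
        if cfg_path.exists():
            config = json.loads(cfg_path.read_text())
        recordings = []
        for row in manifest.itertuples():
            path = indir / row.file
            with open(path) as fh:
                header = fh.readline()
            if not header.startswith("# fs="):
                raise ValueError(f"{path}: missing '# fs=' header comment")
            fs = float(header.strip().split("=", 1)[1])
            samples = pd.read_csv(path, comment="#")["ppg"].to_numpy()
            recordings.append(
                PPGRecording(samples=samples, fs=fs,
                             subject_id=str(row.subject_id), condition=row.condition)
            )
        return cls(recordings=recordings, config=config)
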