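"""Reading and writing single-channel EEG records in the Bonn plain-text layout.

The Bonn epilepsy corpus stores each 23.6 s EEG segment as one ASCII file with
one integer sample per line, sampled at 173.61 Hz, organised in five subset
directories:

=======  =============================  ==========
subset   condition                      Bonn alias
=======  =============================  ==========
Z        healthy, scalp, eyes closed    SET A
O        healthy, scalp, eyes open      SET B
N        interictal, intracranial       SET C
F        interictal, intracranial       SET D
S        ictal, intracranial            SET E
=======  =============================  ==========

Classification tasks are expressed as a :class:`TaskSpec`: an ordered list of
disjoint subset groups, each group becoming one class.  The registry
:data:`TASKS` holds the nine standard tasks (eight binary, one ternary
``{F/N}`` vs ``{O/Z}`` vs ``{S}``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SUBSETS",
    "BONN_ALIASES",
    "DEFAULT_FS",
    "BonnFormatError",
    "EEGRecord",
    "TaskSpec",
    "TASKS",
    "read_record_file",
    "write_record_file",
    "load_task_dataset",
]

SUBSETS = ("Z", "O", "N", "F", "S")

#: Directory-name aliases used by the original Bonn distribution.
BONN_ALIASES: Mapping[str, str] = {
    "A": "Z", "SETA": "Z",
    "B": "O", "SETB": "O",
    "C": "N", "SETC": "N",
    "D": "F", "SETD": "F",
    "E": "S", "SETE": "S",
}

DEFAULT_FS = 173.61


class BonnFormatError(ValueError):
    """Raised when a record file or dataset layout cannot be parsed."""


@dataclass
class EEGRecord:
    """One single-channel EEG trace.

    Parameters
    ----------
    samples : numpy.ndarray
        Amplitude values in the units stored on disk (arbitrary ADC units).
    fs : float
        Sampling rate in Hz.
    subset : str
        One of ``Z/O/N/F/S``, or ``"?"`` when the subset is unknown.
    source_id : str
        File stem or synthetic identifier.
    """

    samples: np.ndarray
    fs: float = DEFAULT_FS
    subset: str = "?"
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("EEGRecord requires a non-empty 1-D sample vector")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.subset != "?" and self.subset not in SUBSETS:
            raise ValueError(f"unknown subset code {self.subset!r}")

    def __len__(self) -> int:
        return int(self.samples.size)


@dataclass(frozen=True)
class TaskSpec:
    """A classification task: an ordered list of disjoint subset groups.

    The position of a group in ``groups`` is its class index, e.g. the
    ternary task ``[{F,N}, {O,Z}, {S}]`` labels interictal records 0, healthy
    records 1 and ictal records 2.
    """

    name: str
    groups: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        groups = tuple(frozenset(g) for g in self.groups)
        object.__setattr__(self, "groups", groups)
        if len(groups) < 2:
            raise ValueError("a task needs at least two groups")
        seen: set[str] = set()
        for g in groups:
            if not g:
                raise ValueError("empty group in task spec")
            for code in g:
                if code not in SUBSETS:
                    raise ValueError(f"unknown subset code {code!r} in task {self.name!r}")
                if code in seen:
                    raise ValueError(f"subset {code!r} appears in two groups of task {self.name!r}")
                seen.add(code)

    @property
    def n_classes(self) -> int:
        return len(self.groups)

    @property
    def subsets(self) -> frozenset[str]:
        return frozenset().union(*self.groups)

    def group_label(self, index: int) -> str:
        """Human-readable group name, e.g. ``"{F/N}"``."""
        return "{" + "/".join(sorted(self.groups[index])) + "}"

    def class_of(self, subset: str) -> int | None:
        for i, g in enumerate(self.groups):
            if subset in g:
                return i
        return None


def _task(name: str, *groups: str) -> TaskSpec:
    return TaskSpec(name, tuple(frozenset(g) for g in groups))


#: The nine standard Bonn tasks (class 0 listed first).
TASKS: Mapping[str, TaskSpec] = {
    t.name: t
    for t in (
        _task("Z_vs_S", "Z", "S"),
        _task("O_vs_S", "O", "S"),
        _task("N_vs_S", "N", "S"),
        _task("F_vs_S", "F", "S"),
        _task("ZO_vs_S", "ZO", "S"),
        _task("NF_vs_S", "NF", "S"),
        _task("ZO_vs_NF", "ZO", "NF"),
        _task("FNOZ_vs_S", "FNOZ", "S"),
        _task("ternary", "FN", "OZ", "S"),
    )
}


def read_record_file(path: str | os.PathLike, fs: float = DEFAULT_FS) -> EEGRecord:
    """Read one Bonn-format record: one ASCII sample value per line.

    Blank lines are skipped.  The subset code is inferred from the first
    character of the file name when it is one of ``Z/O/N/F/S`` (case
    insensitive), otherwise the record is marked ``"?"``.
    """
    path = Path(path)
    samples: list[float] = []
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                samples.append(float(text))
            except ValueError:
                raise BonnFormatError(
                    f"{path}: line {lineno}: not a numeric sample: {text!r}"
                ) from None
    if not samples:
        raise BonnFormatError(f"{path}: empty record file")
    first = path.stem[:1].upper()
    subset = first if first in SUBSETS else "?"
    return EEGRecord(np.array(samples), fs=fs, subset=subset, source_id=path.stem)


def write_record_file(record: EEGRecord, path: str | os.PathLike) -> None:
    """Write a record in Bonn plain-text form, one sample per line.

    Integer-valued samples are written without a decimal point, so writing
    then reading is the identity on integer-valued data.
    """
    if record.samples.size < 1:  # defensive; EEGRecord already forbids this
        raise ValueError("refusing to write an empty record")
    path = Path(path)
    lines = []
    for v in record.samples:
        v = float(v)
        lines.append(str(int(v)) if v.is_integer() else repr(v))
    try:
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write record to {path}: {exc}") from exc


def _resolve_subset_dirs(
    root: Path, needed: frozenset[str], alias_map: Mapping[str, str]
) -> dict[str, Path]:
    found: dict[str, Path] = {}
    for entry in sorted(root.iterdir()):
        if not entry.is_dir():
            continue
        key = entry.name.upper().replace(" ", "").replace("_", "")
        code = key if key in SUBSETS else alias_map.get(key)
        if code in needed and code not in found:
            found[code] = entry
    return found


def load_task_dataset(
    root: str | os.PathLike,
    task: TaskSpec,
    fs: float = DEFAULT_FS,
    alias_map: Mapping[str, str] = BONN_ALIASES,
) -> list[tuple[EEGRecord, int]]:
    """Load every record needed by *task* from a Bonn-layout directory tree.

    ``root`` must contain one directory per subset used by the task; names are
    matched case-insensitively, with the original ``SET A``.. ``SET E`` aliases
    accepted via *alias_map*.  Records are labelled with the index of the task
    group containing their subset; subsets outside the task are ignored.
    Ordering is deterministic: sorted by subset code, then file name.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} is not a directory")
    dirs = _resolve_subset_dirs(root, task.subsets, alias_map)
    missing = sorted(task.subsets - dirs.keys())
    if missing:
        raise BonnFormatError(
            f"dataset root {root} is missing subset director{'y' if len(missing)==1 else 'ies'}: "
            + ", ".join(missing)
        )
    out: list[tuple[EEGRecord, int]] = []
    for subset in sorted(task.subsets):
        label = task.class_of(subset)
        assert label is not None
        for fname in sorted(p.name for p in dirs[subset].iterdir() if p.is_file()):
            rec = read_record_file(dirs[subset] / fname, fs=fs)
            rec.subset = subset
            out.append((rec, label))
    return out
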