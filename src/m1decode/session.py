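"""Session container: raw spike times, hand trajectory, and trial table.

A *session* is the unit of analysis: simultaneously recorded spike event
times from an ensemble of motor-cortex units, the hand position sampled on
a uniform time grid, and a chronological table of reach trials.  Sessions
are stored in a single hierarchical HDF5 file with groups
``/units/<k>/spike_times``, ``/hand/{t,x,y}`` and a ``/trials`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

SCHEMA_VERSION = 1

__all__ = [
    "Session",
    "Trial",
    "TrialSplit",
    "SchemaError",
    "ValidationError",
    "read_session",
    "write_session",
    "split_trials",
]


class SchemaError(Exception):
    """Container file does not match the expected layout/version."""


class ValidationError(Exception):
    """Session content violates an invariant."""


@dataclass(frozen=True)
class Trial:
    """One reach trial: [start_s, end_s) with a target label.

    ``label`` is a target identifier (e.g. ``"t3"`` for the fourth
    center-out target) or ``"sequence"`` for random sequential reaches.
    """

    start_s: float
    end_s: float
    label: str


@dataclass
class Session:
    """Raw recording: per-unit spike times, hand positions, trial table.

    Attributes
    ----------
    units : list of 1-D float arrays
        Ascending spike event times (seconds) per unit.
    hand_t, hand_x, hand_y : 1-D float arrays
        Uniformly sampled hand position (cm) and its time stamps (s).
    trials : list of Trial
        Non-overlapping, chronologically ordered.
    session_id : str
    duration_s : float
    meta : dict
        Free-form extras (e.g. generator seed); values must be scalars
        or strings.
    """

    units: list[np.ndarray]
    hand_t: np.ndarray
    hand_x: np.ndarray
    hand_y: np.ndarray
    trials: list[Trial]
    session_id: str
    duration_s: float
    meta: dict = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def validate(self) -> None:
        """Raise ValidationError on any invariant violation."""
        if self.duration_s <= 0:
            raise ValidationError("duration_s must be positive")
        for k, st in enumerate(self.units):
            st = np.asarray(st)
            if st.size and (st.min() < 0 or st.max() > self.duration_s):
                raise ValidationError(
                    f"unit {k}: spike times outside [0, duration_s]"
                )
            if st.size > 1 and np.any(np.diff(st) < 0):
                raise ValidationError(f"unit {k}: spike times decrease")
        t = np.asarray(self.hand_t)
        if t.size < 2:
            raise ValidationError("hand trajectory needs >= 2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValidationError("hand timestamps must strictly increase")
        if np.ptp(dt) > 1e-9:
            raise ValidationError("hand sampling grid is not uniform")
        if not (len(self.hand_x) == len(self.hand_y) == t.size):
            raise ValidationError("hand arrays have mismatched lengths")
        prev_end = -np.inf
        for i, tr in enumerate(self.trials):
            if tr.end_s <= tr.start_s:
                raise ValidationError(f"trial {i}: end <= start")
            if tr.start_s < prev_end - 1e-12:
                raise ValidationError(f"trial {i}: overlaps previous trial")
            if tr.start_s < 0 or tr.end_s > self.duration_s + 1e-9:
                raise ValidationError(f"trial {i}: outside session bounds")
            prev_end = tr.end_s


@dataclass(frozen=True)
class TrialSplit:
    """Chronological train/test partition of trial indices."""

    train_ids: tuple[int, ...]
    test_ids: tuple[int, ...]


def write_session(session: Session, path) -> None:
    """Write a Session to an HDF5 container.

    Writes are byte-stable: the same Session always produces an
    identical file (object timestamps disabled).
    """
    session.validate()
    if session.n_trials == 0:
        raise ValidationError("refusing to write a session with 0 trials")
    opts = dict(track_times=False)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["session_id"] = session.session_id
        f.attrs["duration_s"] = float(session.duration_s)
        for key, val in sorted(session.meta.items()):
            f.attrs[f"meta_{key}"] = val
        g = f.create_group("units")
        width = max(4, len(str(session.n_units)))
        for k, st in enumerate(session.units):
            g.create_dataset(
                f"u{k:0{width}d}", data=np.asarray(st, dtype=np.float64), **opts
            )
        f.create_dataset("hand/t", data=np.asarray(session.hand_t, float), **opts)
        f.create_dataset("hand/x", data=np.asarray(session.hand_x, float), **opts)
        f.create_dataset("hand/y", data=np.asarray(session.hand_y, float), **opts)
        f.create_dataset(
            "trials/start_s",
            data=np.array([tr.start_s for tr in session.trials], float),
            **opts,
        )
        f.create_dataset(
            "trials/end_s",
            data=np.array([tr.end_s for tr in session.trials], float),
            **opts,
        )
        f.create_dataset(
            "trials/label",
            data=np.array([tr.label for tr in session.trials], dtype="S32"),
            **opts,
        )


def read_session(path) -> Session:
    """Read and validate a Session container."""
    with h5py.File(path, "r") as f:
        if f.attrs.get("schema_version") != SCHEMA_VERSION:
            raise SchemaError(
                f"unrecognized schema version {f.attrs.get('schema_version')!r}"
            )
        for group in ("units", "hand", "trials"):
            if group not in f:
                raise SchemaError(f"missing group /{group}")
        units = [f["units"][k][()] for k in sorted(f["units"])]
        meta = {
            key[5:]: (val.item() if hasattr(val, "item") else val)
            for key, val in f.attrs.items()
            if key.startswith("meta_")
        }
        trials = [
            Trial(float(s), float(e), lab.decode())
            for s, e, lab in zip(
                f["trials/start_s"][()],
                f["trials/end_s"][()],
                f["trials/label"][()],
            )
        ]
        session = Session(
            units=units,
            hand_t=f["hand/t"][()],
            hand_x=f["hand/x"][()],
            hand_y=f["hand/y"][()],
            trials=trials,
            session_id=str(f.attrs["session_id"]),
            duration_s=float(f.attrs["duration_s"]),
            meta=meta,
        )
    session.validate()
    return session


def split_trials(session: Session, train_frac: float = 0.75) -> TrialSplit:
    """Chronological train/test split of trials.

    The first ``floor(train_frac * n_trials)`` trials are training; the
    remainder are test.  All model fitting downstream uses the training
    portion only.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    n = session.n_trials
    if n < 2:
        raise ValueError("need at least 2 trials to split")
    n_train = int(np.floor(train_frac * n))
    return TrialSplit(
        train_ids=tuple(range(n_train)), test_ids=tuple(range(n_train, n))
    )
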