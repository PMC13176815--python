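"""Trial-level data model: one row per trial, participant-constant labels.

The canonical container is :class:`TrialTable`, holding the dataset
``D = {(x_i, y_i, p_i, t_i)}``: a feature vector per trial, a binary label,
the participant the trial belongs to, and the trial's 1-based index within
that participant. Row order is authoritative — splitters never sort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

RESERVED_COLUMNS = ("participant_id", "trial_index", "label")


class SchemaError(ValueError):
    """A required column is missing or a reserved name is misused."""


class ValidationError(ValueError):
    """The table violates a TrialTable invariant."""


@dataclass
class TrialTable:
    """Feature table for repeated-measures classification.

    Parameters
    ----------
    features : ndarray of shape (n_trials, n_features)
        Real-valued trial features.
    labels : ndarray of shape (n_trials,)
        Binary class per trial, values in {0, 1}. Labels are constant
        within a participant in the intended use (a participant-level
        outcome), but the container does not force this.
    participant_ids : ndarray of shape (n_trials,)
        Categorical participant identifier per trial (stored as str).
    trial_indices : ndarray of shape (n_trials,)
        1-based index of the trial within its participant.
    feature_names : list of str, length n_features
    """

    features: np.ndarray
    labels: np.ndarray
    participant_ids: np.ndarray
    trial_indices: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValidationError("features must be a 2-D matrix")
        self.labels = np.asarray(self.labels)
        self.participant_ids = np.asarray(self.participant_ids, dtype=object)
        self.trial_indices = np.asarray(self.trial_indices, dtype=int)
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(self.features.shape[1])]
        # Construction checks shape only; invariant checking is the job of
        # validate(), which reports rather than raises so that broken tables
        # can be diagnosed.
        n = self.features.shape[0]
        for name, vec in (
            ("labels", self.labels),
            ("participant_ids", self.participant_ids),
            ("trial_indices", self.trial_indices),
        ):
            if len(vec) != n:
                raise ValidationError(
                    f"length mismatch: {name} has {len(vec)} entries, expected {n}"
                )

    @property
    def n_trials(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def participants(self) -> np.ndarray:
        """Unique participant IDs in ascending order."""
        return np.unique(self.participant_ids.astype(str))

    def subset(self, rows) -> "TrialTable":
        """Row-subset preserving order of ``rows``."""
        rows = np.asarray(rows, dtype=int)
        return TrialTable(
            features=self.features[rows],
            labels=self.labels[rows],
            participant_ids=self.participant_ids[rows],
            trial_indices=self.trial_indices[rows],
            feature_names=list(self.feature_names),
        )

    def select_features(self, names) -> "TrialTable":
        """Column-subset to the named features, in the given order."""
        idx = [self.feature_names.index(n) for n in names]
        return replace(
            self,
            features=self.features[:, idx],
            feature_names=list(names),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        df.insert(0, "trial_index", self.trial_indices)
        df.insert(0, "participant_id", self.participant_ids.astype(str))
        return df

    def __eq__(self, other) -> bool:  # field-by-field, exact
        if not isinstance(other, TrialTable):
            return NotImplemented
        return (
            self.feature_names == other.feature_names
            and np.array_equal(self.features, other.features)
            and np.array_equal(self.labels, other.labels)
            and np.array_equal(
                self.participant_ids.astype(str), other.participant_ids.astype(str)
            )
            and np.array_equal(self.trial_indices, other.trial_indices)
        )


def validate(table: TrialTable) -> list[str]:
    """Check TrialTable invariants; return a (possibly empty) list of violations.

    Reports, never raises: each violation names the broken invariant and the
    offending participants/rows.
    """
    problems: list[str] = []
    n = table.features.shape[0]
    if n == 0:
        problems.append("empty table: n_trials must be > 0")
        return problems
    if table.features.shape[1] == 0:
        problems.append("n_features must be >= 1")
    for name, vec in (
        ("labels", table.labels),
        ("participant_ids", table.participant_ids),
        ("trial_indices", table.trial_indices),
    ):
        if len(vec) != n:
            problems.append(f"length mismatch: {name} has {len(vec)} entries, expected {n}")
    bad = [i for i, v in enumerate(np.asarray(table.labels).ravel()) if v not in (0, 1)]
    if bad:
        problems.append(f"labels must be in {{0, 1}}; offending rows {bad[:10]}")
    if len(set(table.feature_names)) != len(table.feature_names):
        problems.append("feature_names are not unique")
    if not np.all(np.isfinite(table.features)):
        rows = np.unique(np.where(~np.isfinite(table.features))[0]).tolist()
        problems.append(f"non-finite feature values in rows {rows[:10]}")
    # trial_indices unique within participant
    if len(table.trial_indices) == n and len(table.participant_ids) == n:
        df = pd.DataFrame(
            {
                "p": table.participant_ids.astype(str),
                "t": table.trial_indices,
            }
        )
        dup = df[df.duplicated()]
        if not dup.empty:
            who = sorted(dup["p"].unique().tolist())
            problems.append(f"duplicate trial_index within participant(s) {who}")
    return problems


def read_trial_table(path, schema: dict | None = None) -> TrialTable:
    """Read a trial table from a CSV file.

    Expected columns: ``participant_id``, ``label``, optionally
    ``trial_index``, and at least one feature column. ``schema`` maps the
    canonical names to the file's column names, e.g.
    ``{"participant_id": "subject", "label": "fear"}``. When the trial-index
    column is absent, indices are synthesized as the 1-based running count of
    each participant's rows in file order.
    """
    schema = dict(schema or {})
    df = pd.read_csv(path, float_precision="round_trip")
    rename = {v: k for k, v in schema.items() if v in df.columns}
    df = df.rename(columns=rename)
    for col in ("participant_id", "label"):
        if col not in df.columns:
            raise SchemaError(f"required column '{col}' missing from {path}")
    feature_cols = [c for c in df.columns if c not in RESERVED_COLUMNS]
    if not feature_cols:
        raise SchemaError(f"no feature columns found in {path}")
    feats = np.empty((len(df), len(feature_cols)), dtype=float)
    for j, c in enumerate(feature_cols):
        col = pd.to_numeric(df[c], errors="coerce")
        if col.isna().any() and not df[c].isna().any():
            row = int(col.index[col.isna()][0])
            raise ValueError(f"non-numeric feature value at row {row}, column '{c}'")
        feats[:, j] = col.to_numpy(dtype=float)
    labels = df["label"].to_numpy()
    bad = [v for v in np.unique(labels) if v not in (0, 1)]
    if bad:
        raise ValidationError(f"labels must be binary 0/1; found {bad}")
    pids = df["participant_id"].astype(str).to_numpy(dtype=object)
    if "trial_index" in df.columns:
        tidx = df["trial_index"].to_numpy(dtype=int)
    else:
        tidx = (df.groupby("participant_id", sort=False).cumcount() + 1).to_numpy()
    return TrialTable(
        features=feats,
        labels=labels.astype(int),
        participant_ids=pids,
        trial_indices=tidx,
        feature_names=feature_cols,
    )


def write_trial_table(table: TrialTable, path) -> None:
    """Write a trial table as CSV (RFC 4180 quoting, header row, UTF-8).

    Round-trips exactly through :func:`read_trial_table`.
    """
    problems = validate(table)
    if problems:
        raise ValidationError("; ".join(problems))
    if table.n_features == 0:
        raise ValidationError("cannot write a table with zero features")
    # repr() is the shortest representation that round-trips a float exactly
    table.to_dataframe().to_csv(
        path, index=False, encoding="utf-8", float_format=lambda v: repr(float(v))
    )
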