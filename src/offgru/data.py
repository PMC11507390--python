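"""Dataset I/O, the bundled benchmark manifest, balanced bootstrap
batching, and the three evaluation split protocols.

Off-target benchmark tables are flat CSV/TSV files with one aligned
sgRNA-DNA pair per row.  Splits come in three flavours used throughout
the field:

* ``holdout_85_15`` — single stratified 85/15 train/test split;
* ``kfold_5`` — stratified five-fold cross-validation;
* ``leave_one_guide_out`` — one fold per distinct sgRNA, so train and
  test never share a guide (guards against guide-level leakage).

Training batches are drawn by balanced bootstrap: each batch holds
exactly half positives and half negatives, sampled with replacement
within each class, which keeps gradient updates stable at imbalance
ratios in the thousands.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import StratifiedKFold, train_test_split

from .encoding import GuidePair, validate_pair

SPLIT_KINDS = ("holdout_85_15", "kfold_5", "leave_one_guide_out")

DEFAULT_COLUMNS = {"guide_id": "guide_id", "guide_seq": "sgRNA",
                   "target_seq": "DNA", "label": "label"}


class DatasetError(ValueError):
    pass


@dataclass(frozen=True)
class DatasetManifest:
    """Summary of one dataset: counts, imbalance ratio, category."""

    name: str
    cell_type: str = ""
    n_positive: int = 0
    n_negative: int = 0
    imbalance_ratio: float = 0.0
    category: str = "mismatch"
    flagged: bool = False
    ir_decimals: int = 1  # precision the ratio is recorded at

    @property
    def recomputed_ir(self) -> float:
        """Imbalance ratio recomputed from the counts at the recorded
        precision."""
        if self.n_positive == 0:
            return math.inf
        return round(self.n_negative / self.n_positive, self.ir_decimals)

    @property
    def consistent(self) -> bool:
        return math.isclose(self.recomputed_ir, self.imbalance_ratio,
                            abs_tol=0.5 * 10 ** -self.ir_decimals)


def bundled_manifests() -> list[DatasetManifest]:
    """The packaged manifest of published benchmark datasets."""
    text = (importlib.resources.files("offgru") / "table_manifest.yaml").read_text()
    raw = yaml.safe_load(text)
    return [DatasetManifest(**entry) for entry in raw["datasets"]]


def manifest_from_pairs(pairs: list[GuidePair], name: str = "") -> DatasetManifest:
    n_pos = sum(p.label for p in pairs)
    n_neg = len(pairs) - n_pos
    ir = round(n_neg / n_pos, 1) if n_pos else math.inf
    category = ("mismatch_and_indel" if any(p.has_indel for p in pairs)
                else "mismatch")
    return DatasetManifest(name=name, n_positive=n_pos, n_negative=n_neg,
                           imbalance_ratio=ir, category=category)


def load_dataset(path, columns: dict[str, str] | None = None,
                 name: str | None = None
                 ) -> tuple[list[GuidePair], DatasetManifest]:
    """Read a CSV/TSV of aligned pairs and validate every record.

    ``columns`` remaps the expected logical fields (guide_id, guide_seq,
    target_seq, label) onto the file's header names.  Rows violating the
    alignment invariants are collected and reported together.
    """
    cols = dict(DEFAULT_COLUMNS)
    cols.update(columns or {})
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DatasetError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in (cols["guide_seq"], cols["target_seq"], cols["label"])
               if c not in df.columns]
    if missing:
        raise DatasetError(f"{path}: missing required columns {missing}")
    has_id = cols["guide_id"] in df.columns

    pairs: list[GuidePair] = []
    problems: list[str] = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        try:
            label = int(rec[cols["label"]])
        except (TypeError, ValueError):
            problems.append(f"row {row_number}: non-integer label "
                            f"{rec[cols['label']]!r}")
            continue
        pair = GuidePair(
            guide_seq=str(rec[cols["guide_seq"]]).upper(),
            target_seq=str(rec[cols["target_seq"]]).upper(),
            label=label,
            guide_id=str(rec[cols["guide_id"]]) if has_id else "",
        )
        violations = validate_pair(pair)
        if violations:
            problems.append(f"row {row_number}: " + "; ".join(violations))
        else:
            pairs.append(pair)
    if problems:
        raise DatasetError(
            f"{path}: {len(problems)} invalid rows:\n" + "\n".join(problems)
        )
    manifest = manifest_from_pairs(
        pairs, name=name or str(path).rsplit("/", 1)[-1].rsplit(".", 1)[0]
    )
    return pairs, manifest


def save_dataset(pairs: list[GuidePair], path,
                 columns: dict[str, str] | None = None) -> None:
    cols = dict(DEFAULT_COLUMNS)
    cols.update(columns or {})
    df = pd.DataFrame({
        cols["guide_id"]: [p.guide_id for p in pairs],
        cols["guide_seq"]: [p.guide_seq for p in pairs],
        cols["target_seq"]: [p.target_seq for p in pairs],
        cols["label"]: [p.label for p in pairs],
    })
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df.to_csv(path, sep=sep, index=False)


# ----------------------------------------------------------------------
# Balanced bootstrap batching
# ----------------------------------------------------------------------

def balanced_bootstrap_batches(labels: np.ndarray, batch_size: int,
                               rng: np.random.Generator | int):
    """Yield index arrays for one epoch of balanced bootstrap batches.

    Every batch holds exactly ``batch_size/2`` positives and
    ``batch_size/2`` negatives drawn with replacement from the respective
    class; minority records therefore recur many times per epoch at high
    imbalance.  Epoch length is ``ceil(n / batch_size)`` batches.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    labels = np.asarray(labels).ravel()
    if batch_size < 2 or batch_size % 2:
        raise ValueError("batch_size must be a positive even number")
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if pos.size == 0 or neg.size == 0:
        raise ValueError(
            "balanced sampling needs at least one record of each class "
            f"(got {pos.size} positives, {neg.size} negatives)"
        )
    half = batch_size // 2
    n_batches = math.ceil(labels.size / batch_size)
    for _ in range(n_batches):
        batch = np.concatenate([rng.choice(pos, size=half, replace=True),
                                rng.choice(neg, size=half, replace=True)])
        rng.shuffle(batch)
        yield batch


# ----------------------------------------------------------------------
# Split protocols
# ----------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Fold assignment for one evaluation protocol.

    ``assignments`` maps record index -> fold number.  For the holdout
    protocol fold 0 is the training set and fold 1 the test set; for the
    k-fold and leave-one-guide-out protocols each fold in turn is the test
    set and the others train.
    """

    kind: str
    assignments: np.ndarray
    seed: int
    fold_names: list[str] = field(default_factory=list)

    @property
    def n_folds(self) -> int:
        return int(self.assignments.max()) + 1

    def folds(self):
        """Yield (fold_number, train_indices, test_indices)."""
        idx = np.arange(self.assignments.size)
        if self.kind == "holdout_85_15":
            yield 0, idx[self.assignments == 0], idx[self.assignments == 1]
            return
        for f in range(self.n_folds):
            yield f, idx[self.assignments != f], idx[self.assignments == f]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"index": np.arange(self.assignments.size),
                             "fold": self.assignments})


def make_split(records: list[GuidePair], kind: str, seed: int = 0) -> SplitPlan:
    """Build a split plan of the requested kind.

    Holdout and five-fold splits are stratified by label so that test
    folds keep a positive fraction close to the global one, which matters
    at extreme imbalance.  ``leave_one_guide_out`` produces one fold per
    distinct ``guide_id``.
    """
    if kind not in SPLIT_KINDS:
        raise ValueError(f"unknown split kind {kind!r}; valid: {SPLIT_KINDS}")
    n = len(records)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    labels = np.array([p.label for p in records])
    assignments = np.zeros(n, dtype=int)

    if kind == "holdout_85_15":
        idx = np.arange(n)
        stratify = labels if labels.min() != labels.max() else None
        _, test_idx = train_test_split(idx, test_size=0.15, random_state=seed,
                                       stratify=stratify)
        assignments[test_idx] = 1
        return SplitPlan(kind, assignments, seed, ["train", "test"])

    if kind == "kfold_5":
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
        for f, (_, test_idx) in enumerate(skf.split(np.zeros(n), labels)):
            assignments[test_idx] = f
        return SplitPlan(kind, assignments, seed,
                         [f"fold{f}" for f in range(5)])

    guides = np.array([p.guide_id for p in records])
    unique = sorted(set(guides))
    if len(unique) < 2:
        raise ValueError(
            "leave_one_guide_out needs at least two distinct guide_ids, "
            f"found {len(unique)}"
        )
    for f, g in enumerate(unique):
        assignments[guides == g] = f
    return SplitPlan(kind, assignments, seed, list(unique))
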