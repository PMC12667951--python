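"""Reading, transforming and splitting paired-platform matrices.

The central container is :class:`PairedPlatformMatrix`: two sample-aligned
numeric matrices (samples x probes), one per affinity-proteomics platform
(e.g. Olink NPX, already on a log2 scale, and SomaScan RFU, log2-transformed
here), plus optional one-to-one probe correspondences across platforms.

Preprocessing follows the standard harmonisation recipe: log2 transform
where needed, then feature-wise Z-scoring so every probe has mean 0 and
SD 1. Standardisation parameters applied to a cohort are always fit on that
cohort's own distribution; applying foreign parameters requires an explicit
override (see :func:`guard_cohort_params`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass
class PlatformMatrix:
    """One platform's samples x probes matrix with IDs in file order."""

    samples: list[str]
    probes: list[str]
    values: np.ndarray  # N x d, NaN marks missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.samples), len(self.probes)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.probes)} probes"
            )
        for name, ids in (("sample", self.samples), ("probe", self.probes)):
            dupes = _duplicates(ids)
            if dupes:
                raise ValueError(f"duplicate {name} IDs: {sorted(dupes)}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.probes)


@dataclass
class PairedPlatformMatrix:
    """Two sample-aligned platform matrices plus optional probe matches."""

    samples: list[str]
    platform_a: np.ndarray
    platform_b: np.ndarray
    probes_a: list[str]
    probes_b: list[str]
    probe_map: Optional[list[tuple[str, str]]] = None

    def __post_init__(self) -> None:
        self.platform_a = np.asarray(self.platform_a, dtype=np.float64)
        self.platform_b = np.asarray(self.platform_b, dtype=np.float64)
        n = len(self.samples)
        if self.platform_a.shape[0] != n or self.platform_b.shape[0] != n:
            raise ValueError("platform matrices must have one row per sample")
        if self.platform_a.shape[1] != len(self.probes_a):
            raise ValueError("platform A width does not match probesA")
        if self.platform_b.shape[1] != len(self.probes_b):
            raise ValueError("platform B width does not match probesB")
        for name, ids in (("probesA", self.probes_a), ("probesB", self.probes_b)):
            dupes = _duplicates(ids)
            if dupes:
                raise ValueError(f"duplicate IDs in {name}: {sorted(dupes)}")
        if self.probe_map is not None:
            set_a, set_b = set(self.probes_a), set(self.probes_b)
            seen_a: set[str] = set()
            seen_b: set[str] = set()
            for pa, pb in self.probe_map:
                if pa not in set_a or pb not in set_b:
                    raise ValueError(f"probe_map entry ({pa}, {pb}) references unknown probes")
                if pa in seen_a or pb in seen_b:
                    raise ValueError(f"probe appears twice in probe_map: ({pa}, {pb})")
                seen_a.add(pa)
                seen_b.add(pb)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def half(self, platform: str) -> PlatformMatrix:
        if platform == "A":
            return PlatformMatrix(list(self.samples), list(self.probes_a), self.platform_a.copy())
        if platform == "B":
            return PlatformMatrix(list(self.samples), list(self.probes_b), self.platform_b.copy())
        raise ValueError("platform must be 'A' or 'B'")


@dataclass
class StandardizationParams:
    """Per-probe mean/SD (sample SD, ddof=1) with cohort provenance."""

    probes: list[str]
    mean: np.ndarray
    sd: np.ndarray
    cohort: str = "unknown"

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.sd = np.asarray(self.sd, dtype=np.float64)
        if not (len(self.probes) == self.mean.size == self.sd.size):
            raise ValueError("probes, mean and sd must have equal lengths")
        if np.any(self.sd <= 0):
            bad = [p for p, s in zip(self.probes, self.sd) if s <= 0]
            raise ValueError(f"non-positive SD for probes: {bad}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "probes": self.probes,
                    "mean": self.mean.tolist(),
                    "sd": self.sd.tolist(),
                    "cohort": self.cohort,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "StandardizationParams":
        d = json.loads(Path(path).read_text())
        return cls(probes=d["probes"], mean=d["mean"], sd=d["sd"], cohort=d["cohort"])


@dataclass
class SplitAssignment:
    """Disjoint, exhaustive train / early-stop / tune / test index sets."""

    train: np.ndarray
    early_stop: np.ndarray
    tune: np.ndarray
    test: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        sets = [np.asarray(s, dtype=np.intp) for s in (self.train, self.early_stop, self.tune, self.test)]
        self.train, self.early_stop, self.tune, self.test = sets
        allidx = np.concatenate(sets)
        if len(np.unique(allidx)) != allidx.size:
            raise ValueError("split sets overlap")

    @property
    def n(self) -> int:
        return self.train.size + self.early_stop.size + self.tune.size + self.test.size

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "train": self.train.tolist(),
                    "early_stop": self.early_stop.tolist(),
                    "tune": self.tune.tolist(),
                    "test": self.test.tolist(),
                    "seed": self.seed,
                },
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitAssignment":
        d = json.loads(Path(path).read_text())
        return cls(
            train=np.array(d["train"]), early_stop=np.array(d["early_stop"]),
            tune=np.array(d["tune"]), test=np.array(d["test"]), seed=d["seed"],
        )


def _duplicates(ids: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for i in ids:
        if i in seen:
            dup.add(i)
        seen.add(i)
    return dup


# --------------------------------------------------------------------------
# file IO
# --------------------------------------------------------------------------


def read_matrix(
    path: str | Path,
    orientation: str = "samples_rows",
    delimiter: Optional[str] = None,
) -> PlatformMatrix:
    """Read a delimited matrix with an ID header row and ID first column.

    ``orientation='probes_rows'`` transposes on read. The delimiter is
    auto-detected from the extension (.csv -> comma, else tab) unless given.
    Missing cells stay NaN; non-numeric cells raise with row/column names.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(delimiter)[1:]
    dupes = _duplicates(header)
    if dupes:
        raise ValueError(f"duplicate column IDs in {path}: {sorted(dupes)}")
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    df.columns = header
    if orientation == "probes_rows":
        df = df.T
    elif orientation != "samples_rows":
        raise ValueError("orientation must be 'samples_rows' or 'probes_rows'")
    values = np.full(df.shape, np.nan)
    for j, col in enumerate(df.columns):
        parsed = pd.to_numeric(df[col], errors="coerce")
        raw_missing = df[col].isna()
        bad = parsed.isna() & ~raw_missing
        if bad.any():
            row = df.index[np.flatnonzero(bad.values)[0]]
            raise ValueError(f"non-numeric value at row {row!r}, column {col!r} in {path}")
        values[:, j] = parsed.values
    return PlatformMatrix(
        samples=[str(s) for s in df.index],
        probes=[str(p) for p in df.columns],
        values=values,
    )


def write_matrix(half: PlatformMatrix, path: str | Path, delimiter: Optional[str] = None) -> None:
    path = Path(path)
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    half.to_frame().to_csv(path, sep=delimiter, float_format="%.10g")


# --------------------------------------------------------------------------
# transforms
# --------------------------------------------------------------------------


def log2_transform(values: np.ndarray, probes: Optional[Sequence[str]] = None) -> np.ndarray:
    """Elementwise log2; all values must be strictly positive."""
    values = np.asarray(values, dtype=np.float64)
    nonpos = np.nanmin(values, axis=0) <= 0
    if np.any(nonpos):
        if probes is not None:
            bad = [p for p, b in zip(probes, nonpos) if b]
        else:
            bad = np.flatnonzero(nonpos).tolist()
        raise ValueError(f"log2 requires strictly positive values; offending probes: {bad}")
    return np.log2(values)


def zscore_fit(values: np.ndarray, probes: Sequence[str], cohort: str = "unknown") -> StandardizationParams:
    """Fit per-probe mean and sample SD (ddof=1); zero-variance probes raise."""
    values = np.asarray(values, dtype=np.float64)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 samples to fit standardisation")
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    if np.any(sd <= 0) or np.any(~np.isfinite(sd)):
        bad = [p for p, s in zip(probes, sd) if not (s > 0)]
        raise ValueError(f"zero-variance probes (drop before fitting): {bad}")
    return StandardizationParams(probes=list(probes), mean=mean, sd=sd, cohort=cohort)


def zscore_apply(values: np.ndarray, params: StandardizationParams) -> np.ndarray:
    values = np.asarray(values, dtype=np.float64)
    if values.shape[1] != params.mean.size:
        raise ValueError("width mismatch between matrix and standardisation params")
    return (values - params.mean) / params.sd


def zscore_invert(values: np.ndarray, params: StandardizationParams) -> np.ndarray:
    values = np.asarray(values, dtype=np.float64)
    if values.shape[1] != params.mean.size:
        raise ValueError("width mismatch between matrix and standardisation params")
    return values * params.sd + params.mean


def guard_cohort_params(params: StandardizationParams, cohort: str, allow_foreign: bool = False) -> None:
    """Enforce the own-distribution rule: params must come from ``cohort``.

    Each cohort is standardised with parameters derived from its own
    distribution; passing another cohort's parameters raises unless
    explicitly overridden.
    """
    if params.cohort != cohort and not allow_foreign:
        raise ValueError(
            f"standardisation params were fit on cohort {params.cohort!r} but are being "
            f"applied to {cohort!r}; each cohort must use its own distribution "
            f"(fit on the target cohort, or pass allow_foreign=True to override)"
        )


# --------------------------------------------------------------------------
# splits / alignment / probe matching / missingness
# --------------------------------------------------------------------------


def make_splits(
    n: int,
    fractions: Sequence[float] = (0.6, 0.1, 0.1, 0.2),
    seed: int = 0,
) -> SplitAssignment:
    """Random four-way split (train / early-stop / tune / test).

    Sizes are floor(n * fraction) with remainders assigned to the four sets
    in declared order, so the partition is always disjoint and exhaustive.
    """
    if n < 4:
        raise ValueError("need at least 4 samples to split four ways")
    fractions = np.asarray(fractions, dtype=np.float64)
    if fractions.size != 4 or np.any(fractions < 0):
        raise ValueError("fractions must be 4 nonnegative numbers")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions sum to {fractions.sum()}, expected 1")
    sizes = np.floor(fractions * n).astype(int)
    rem = n - sizes.sum()
    for i in range(rem):
        sizes[i % 4] += 1
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    bounds = np.cumsum(sizes)
    return SplitAssignment(
        train=np.sort(perm[: bounds[0]]),
        early_stop=np.sort(perm[bounds[0] : bounds[1]]),
        tune=np.sort(perm[bounds[1] : bounds[2]]),
        test=np.sort(perm[bounds[2] :]),
        seed=seed,
    )


def align_samples(half_a: PlatformMatrix, half_b: PlatformMatrix) -> tuple[PairedPlatformMatrix, list[str]]:
    """Pair the two halves on the intersection of sample IDs.

    Returns the paired matrix (ordered by half A's sample order) and the
    list of sample IDs dropped from either side.
    """
    common = set(half_a.samples) & set(half_b.samples)
    if not common:
        raise ValueError("no shared sample IDs between the two platforms")
    order = [s for s in half_a.samples if s in common]
    idx_a = [half_a.samples.index(s) for s in order]
    pos_b = {s: i for i, s in enumerate(half_b.samples)}
    idx_b = [pos_b[s] for s in order]
    dropped = sorted((set(half_a.samples) | set(half_b.samples)) - common)
    paired = PairedPlatformMatrix(
        samples=order,
        platform_a=half_a.values[idx_a],
        platform_b=half_b.values[idx_b],
        probes_a=list(half_a.probes),
        probes_b=list(half_b.probes),
    )
    return paired, dropped


def match_probes(
    probes_a: Sequence[str],
    probes_b: Sequence[str],
    correspondence: Sequence[tuple[str, str]],
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Filter a correspondence table down to strict one-to-one matches.

    Rows whose probes are absent from either platform, and every row
    involved in a many-to-one conflict, are excluded; the second return
    value reports the excluded rows.
    """
    set_a, set_b = set(probes_a), set(probes_b)
    present = [(pa, pb) for pa, pb in correspondence if pa in set_a and pb in set_b]
    absent = [(pa, pb) for pa, pb in correspondence if not (pa in set_a and pb in set_b)]
    count_a: dict[str, int] = {}
    count_b: dict[str, int] = {}
    for pa, pb in present:
        count_a[pa] = count_a.get(pa, 0) + 1
        count_b[pb] = count_b.get(pb, 0) + 1
    kept = [(pa, pb) for pa, pb in present if count_a[pa] == 1 and count_b[pb] == 1]
    excluded = absent + [(pa, pb) for pa, pb in present if count_a[pa] > 1 or count_b[pb] > 1]
    return kept, excluded


def read_probe_map(path: str | Path, delimiter: str = "\t") -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep=delimiter, header=None, dtype=str, comment="#")
    return [(str(a), str(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])]


def drop_or_impute_missing(half: PlatformMatrix, policy: str = "drop_samples") -> tuple[PlatformMatrix, int]:
    """Handle missing cells: drop whole samples (returning dropped count) or error."""
    mask = np.isnan(half.values).any(axis=1)
    n_missing_rows = int(mask.sum())
    if policy == "error":
        if n_missing_rows:
            raise ValueError(f"{int(np.isnan(half.values).sum())} missing values in {n_missing_rows} samples")
        return half, 0
    if policy == "drop_samples":
        keep = ~mask
        return (
            PlatformMatrix(
                samples=[s for s, k in zip(half.samples, keep) if k],
                probes=list(half.probes),
                values=half.values[keep],
            ),
            n_missing_rows,
        )
    raise ValueError("policy must be 'drop_samples' or 'error'")
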