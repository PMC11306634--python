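"""Correlation and group-separation statistics over complexity profiles.

The analysis stage: tidy per-object records feed pairwise Pearson correlations
(one-tailed, testing positive association) and two-group separation summaries
(rank AUC, Cliff's delta, per-group median and IQR).  ``run_pipeline`` wires
generation, encoding and measurement into one reproducible run with a written
manifest.
"""

from __future__ import annotations

import json
import logging
import math
import sys
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as scipy_stats

from . import measures as measures_mod
from .assembly import assembly_index_exact, assembly_index_greedy, DEFAULT_MAX_LEN
from .ctm_bdm import CTMTable, bdm, load_ctm_table
from .encodings import Sequence, ascii_to_bits
from .errors import DegenerateInputError, InsufficientDataError, InvalidArgumentError
from .synthetic import gen_string_corpus

logger = logging.getLogger("molcomplexity")

__all__ = [
    "ResultsTable",
    "CorrelationReport",
    "SeparationEntry",
    "SeparationReport",
    "pearson_one_tailed",
    "separation",
    "correlation_matrix",
    "run_pipeline",
]


@dataclass
class ResultsTable:
    """Tidy records ``(object_id, group, representation, measure, value)``."""

    records: list[tuple[str, str, str, str, float]] = field(default_factory=list)

    def add(self, object_id: str, group: str, representation: str, measure: str, value: float):
        if not np.isfinite(value):
            raise InvalidArgumentError(f"non-finite value for {object_id}/{measure}")
        key = (object_id, representation, measure)
        if key in self._index:
            raise InvalidArgumentError(f"duplicate record {key}")
        self._index.add(key)
        self.records.append((object_id, group, representation, measure, float(value)))

    def __post_init__(self):
        self._index = {(o, r, m) for o, _, r, m, _ in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records,
            columns=["object_id", "group", "representation", "measure", "value"],
        )


@dataclass(frozen=True)
class CorrelationReport:
    pairs: tuple  # (measure_a, measure_b, r, p_one_tailed, n)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.pairs), columns=["measure_a", "measure_b", "r", "p_one_tailed", "n"]
        )

    def lookup(self, a: str, b: str):
        for ma, mb, r, p, n in self.pairs:
            if {ma, mb} == {a, b}:
                return r, p, n
        raise KeyError((a, b))


@dataclass(frozen=True)
class SeparationEntry:
    measure: str
    groups: tuple[str, str]
    medians: tuple[float, float]
    iqrs: tuple[float, float]
    auc: float
    cliffs_delta: float


@dataclass(frozen=True)
class SeparationReport:
    entries: tuple[SeparationEntry, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            rows.append(
                {
                    "measure": e.measure,
                    "group_a": e.groups[0],
                    "group_b": e.groups[1],
                    "median_a": e.medians[0],
                    "median_b": e.medians[1],
                    "iqr_a": e.iqrs[0],
                    "iqr_b": e.iqrs[1],
                    "auc": e.auc,
                    "cliffs_delta": e.cliffs_delta,
                }
            )
        return pd.DataFrame(rows)

    def lookup(self, measure: str) -> SeparationEntry:
        for e in self.entries:
            if e.measure == measure:
                return e
        raise KeyError(measure)


# ---------------------------------------------------------------------------
# core statistics


def pearson_one_tailed(x, y) -> tuple[float, float]:
    """Product-moment correlation with an upper-tail (positive) p-value.

    ``p`` comes from ``t = r sqrt((n-2)/(1-r^2))`` against Student's t with
    ``n - 2`` degrees of freedom.  Constant inputs raise
    :class:`DegenerateInputError` rather than returning NaN.  p-values are
    uncorrected for multiple testing.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidArgumentError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise InsufficientDataError("need n >= 3 for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("correlation undefined for a constant vector")
    dx = x - x.mean()
    dy = y - y.mean()
    r = float((dx * dy).sum() / math.sqrt((dx * dx).sum() * (dy * dy).sum()))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0 if r > 0 else 1.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = float(scipy_stats.t.sf(t, df=n - 2))
    return r, max(p, sys.float_info.min)


def separation(values, labels) -> SeparationEntry:
    """Two-group rank separation: AUC (ties half-weighted) and Cliff's delta.

    AUC is the Mann-Whitney U statistic divided by ``n1 * n2``, oriented as the
    probability that a member of the second group (sorted label order) exceeds
    a member of the first; relabelling maps ``auc`` to ``1 - auc``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise InvalidArgumentError("values and labels must align")
    groups = sorted(set(labels.tolist()))
    if len(groups) != 2:
        raise InvalidArgumentError(f"separation needs exactly two groups, got {groups}")
    a = values[labels == groups[0]]
    b = values[labels == groups[1]]
    if a.size == 0 or b.size == 0:
        raise InvalidArgumentError("both groups must be non-empty")
    ranks = scipy_stats.rankdata(np.concatenate([a, b]))
    rank_sum_b = ranks[a.size :].sum()
    u_b = rank_sum_b - b.size * (b.size + 1) / 2.0  # wins of group b over a
    auc = float(u_b / (a.size * b.size))
    cliffs = 2.0 * auc - 1.0
    med = (float(np.median(a)), float(np.median(b)))
    iqr = (
        float(np.percentile(a, 75) - np.percentile(a, 25)),
        float(np.percentile(b, 75) - np.percentile(b, 25)),
    )
    return SeparationEntry("", (groups[0], groups[1]), med, iqr, auc, cliffs)


def correlation_matrix(rt: ResultsTable, representation: str) -> CorrelationReport:
    """All measure-pair Pearson correlations, pairwise-complete."""
    df = rt.to_frame()
    df = df[df["representation"] == representation]
    wide = df.pivot(index="object_id", columns="measure", values="value")
    if len(wide.dropna()) < 3:
        raise InsufficientDataError(
            f"fewer than 3 complete objects for representation {representation!r}"
        )
    pairs = []
    for a, b in combinations(sorted(wide.columns), 2):
        sub = wide[[a, b]].dropna()
        dropped = len(wide) - len(sub)
        if dropped:
            logger.info("pair (%s, %s): dropped %d incomplete objects", a, b, dropped)
        if len(sub) < 3:
            raise InsufficientDataError(f"fewer than 3 complete objects for pair ({a}, {b})")
        r, p = pearson_one_tailed(sub[a].to_numpy(), sub[b].to_numpy())
        pairs.append((a, b, r, p, len(sub)))
    return CorrelationReport(tuple(pairs))


# ---------------------------------------------------------------------------
# orchestration


_DEFAULT_CONFIG = {
    "kind": "strings",
    "n_per_class": 100,
    "seed": 42,
    "representation": "raw-text",
    "measures": ["rle", "huffman", "lz78", "lzw", "assembly"],
    "assembly_method": "greedy",  # greedy | exact | auto
    "assembly_exact_max": 14,  # used by "auto"
    "entropy_block": 1,
    "bdm_block": 4,
    "ctm_table": None,  # path; None -> packaged default
    "external_ma": None,  # CSV path: object_id,ma
    "corpus": {},  # overrides for gen_string_corpus
}


def _assembly_scalar(seq: Sequence, method: str, exact_max: int) -> float:
    if method == "exact" or (method == "auto" and len(seq) <= exact_max):
        return assembly_index_exact(seq, max_len=max(DEFAULT_MAX_LEN, len(seq))).index
    return assembly_index_greedy(seq).index


def _measure_value(name: str, seq: Sequence, cfg: dict, ctm: "CTMTable | None") -> float:
    if name == "assembly":
        return _assembly_scalar(seq, cfg["assembly_method"], cfg["assembly_exact_max"])
    if name == "bdm":
        target = seq if seq.is_binary else ascii_to_bits(seq.symbols)
        return bdm(target, ctm, block_length=cfg["bdm_block"]).value
    if name == "entropy":
        return measures_mod.shannon_entropy(seq, block=cfg["entropy_block"])
    try:
        return measures_mod.SCALAR_MEASURES[name](seq)
    except KeyError:
        raise InvalidArgumentError(f"unknown measure {name!r}") from None


@dataclass(frozen=True)
class PipelineResult:
    results: ResultsTable
    correlations: CorrelationReport
    separation: "SeparationReport | None"
    manifest: dict


def run_pipeline(config: dict | None = None, out_dir: "str | Path | None" = None) -> PipelineResult:
    """Generate -> encode -> measure -> statistics, reproducibly.

    The effective config (defaults merged with overrides) and the seed are
    embedded in the returned manifest; with ``out_dir`` set, ``results.csv``,
    ``correlations.csv``, ``separation.csv`` and ``manifest.json`` are written.
    """
    cfg = dict(_DEFAULT_CONFIG)
    cfg.update(config or {})
    if cfg["kind"] != "strings":
        raise InvalidArgumentError("run_pipeline currently orchestrates the string corpus")
    representation = cfg["representation"]

    records = gen_string_corpus(
        n_per_class=cfg["n_per_class"], seed=cfg["seed"], **cfg["corpus"]
    )

    ctm = None
    if "bdm" in cfg["measures"]:
        if cfg["ctm_table"]:
            ctm = load_ctm_table(cfg["ctm_table"])
        else:
            from .ctm_bdm import default_ctm_table

            ctm = default_ctm_table()

    table = ResultsTable()
    for object_id, group, seq in records:
        for name in cfg["measures"]:
            value = _measure_value(name, seq, cfg, ctm)
            table.add(object_id, group, representation, name, value)

    # optional externally supplied assembly values, taken at face value
    if cfg["external_ma"]:
        ma = pd.read_csv(cfg["external_ma"])
        known = {object_id for object_id, _, _ in records}
        unknown = sorted(set(ma["object_id"]) - known)
        if unknown:
            raise InvalidArgumentError(
                f"external MA column references unknown object_ids: {unknown[:5]}"
            )
        group_of = {object_id: group for object_id, group, _ in records}
        for _, row in ma.iterrows():
            table.add(row["object_id"], group_of[row["object_id"]], representation, "MA", float(row["ma"]))

    correlations = correlation_matrix(table, representation)

    df = table.to_frame()
    groups = sorted(df["group"].unique())
    sep = None
    if len(groups) == 2:
        entries = []
        for name in sorted(df["measure"].unique()):
            sub = df[df["measure"] == name]
            entry = separation(sub["value"].to_numpy(), sub["group"].to_numpy())
            entries.append(
                SeparationEntry(name, entry.groups, entry.medians, entry.iqrs, entry.auc, entry.cliffs_delta)
            )
        sep = SeparationReport(tuple(entries))
    else:
        logger.warning("separation report omitted: %d group(s) present", len(groups))

    manifest = {
        "config": {k: v for k, v in cfg.items() if k != "corpus"} | {"corpus": dict(cfg["corpus"])},
        "seed": cfg["seed"],
        "n_objects": len(records),
        "measures": list(cfg["measures"]),
        "p_values": "one-tailed, uncorrected",
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_frame().to_csv(out / "results.csv", index=False)
        correlations.to_frame().to_csv(out / "correlations.csv", index=False)
        if sep is not None:
            sep.to_frame().to_csv(out / "separation.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return PipelineResult(table, correlations, sep, manifest)
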