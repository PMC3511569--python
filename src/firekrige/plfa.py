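"""Phospholipid fatty-acid (PLFA) community metrics.

Takes per-core lipid amount tables (nmol), applies the survey's filtering
rules (cores lacking the ubiquitous lipid 16:0 are removed; only lipids with
chain length < 20 are retained), and derives mole percents plus community
metrics: total lipid abundance, fungi-to-bacteria ratio, Gram-positive and
Gram-negative bacterial marker sums and the i15:0/a15:0 stress ratio.

Lipid names follow the field's shorthand ``[i|a|cy]CHAIN:UNSATS[wN][c|t][2OH]``
— e.g. ``16:0``, ``i15:0``, ``cy17:0``, ``18:1w9c`` — with the iso/anteiso
suffix spelling (``15:0iso``) and unicode ``∶``/``ω`` accepted and
canonicalised.  Chain length is the integer before the colon.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "LipidName",
    "parse_lipid",
    "lipid_columns",
    "filter_cores",
    "mole_percent",
    "fb_ratio",
    "marker_sums",
    "stress_ratio",
    "community_metrics",
    "plot_summary",
    "summarize_metrics",
    "PLFAMetrics",
    "FUNGAL_MARKERS",
    "BACTERIAL_MARKERS",
    "GM_POS_MARKERS",
    "GM_NEG_MARKERS",
]

META_COLUMNS = ("core_id", "x_m", "y_m", "plot")

_SUFFIX_RE = re.compile(r"^(\d+):(\d+)(iso|anteiso)$")
_MAIN_RE = re.compile(r"^(i|a|cy)?(\d+):(\d+?)(?:w(\d+))?(c|t)?(2OH)?$")


@dataclass(frozen=True)
class LipidName:
    """Parsed lipid nomenclature; ``base`` ignores the cis/trans suffix."""

    prefix: str       # "", "i", "a" or "cy"
    chain: int
    unsats: int
    omega: int | None
    geometry: str     # "", "c" or "t"
    hydroxy: bool

    @property
    def canonical(self) -> str:
        s = f"{self.prefix}{self.chain}:{self.unsats}"
        if self.omega is not None:
            s += f"w{self.omega}"
        s += self.geometry
        if self.hydroxy:
            s += "-2OH"
        return s

    @property
    def base(self) -> str:
        s = f"{self.prefix}{self.chain}:{self.unsats}"
        if self.omega is not None:
            s += f"w{self.omega}"
        if self.hydroxy:
            s += "-2OH"
        return s


def parse_lipid(name: str) -> LipidName:
    """Parse a lipid column name; raises ``ValueError`` naming the offending
    column when the name does not follow the grammar."""
    s = str(name).strip().replace("∶", ":").replace("ω", "w").replace(" ", "")
    m = _SUFFIX_RE.match(s)
    if m:
        chain, unsats, kind = m.groups()
        s = ("i" if kind == "iso" else "a") + f"{chain}:{unsats}"
    m = _MAIN_RE.match(s)
    if not m:
        raise ValueError(f"unparseable lipid name: {name!r}")
    prefix, chain, unsats, omega, geom, oh = m.groups()
    return LipidName(
        prefix=prefix or "",
        chain=int(chain),
        unsats=int(unsats),
        omega=int(omega) if omega is not None else None,
        geometry=geom or "",
        hydroxy=oh is not None,
    )


# Marker sets (canonical spellings).  The fungi-to-bacteria ratio is
# (18:1w9c + 16:1w5) / (a15:0 + i15:0 + 15:0 + i16:0 + 15:1w8c + 16:1w7c +
# cy17:0 + a17:0 + 17:1w7c); 16:1w5 has no cis/trans suffix in the formula and
# matches 16:1w5c in data tables (exact-match-first, then suffix-tolerant).
FUNGAL_MARKERS = ("18:1w9c", "16:1w5")
BACTERIAL_MARKERS = (
    "a15:0", "i15:0", "15:0", "i16:0", "15:1w8c", "16:1w7c",
    "cy17:0", "a17:0", "17:1w7c",
)
GM_POS_MARKERS = ("i15:0", "a15:0", "i16:0", "a17:0", "i17:0")
GM_NEG_MARKERS = ("15:1w8", "16:1w7", "17:1w7", "19:1w8t", "15:1w9")


def lipid_columns(table: pd.DataFrame) -> list[str]:
    """Columns of a wide per-core table that hold lipid amounts (everything
    that is not core metadata)."""
    return [c for c in table.columns if c not in META_COLUMNS]


def _resolve_marker(marker: str, parsed: dict[str, LipidName]) -> list[str]:
    """Columns matching one marker: exact canonical match first, otherwise any
    column whose name differs only by the cis/trans suffix."""
    target = parse_lipid(marker)
    exact = [c for c, ln in parsed.items() if ln.canonical == target.canonical]
    if exact:
        return exact
    return [c for c, ln in parsed.items() if ln.base == target.base]


def filter_cores(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the survey's inclusion rules.

    Cores whose 16:0 amount is absent or zero are removed; lipid columns with
    chain length >= 20 are dropped.  Retained values pass through unchanged.
    Returns the filtered table and a report with the removed core ids,
    dropped columns and marker coverage of the retained columns.
    """
    cols = lipid_columns(table)
    parsed = {c: parse_lipid(c) for c in cols}
    keep_cols = [c for c in cols if parsed[c].chain < 20]
    dropped_cols = [c for c in cols if parsed[c].chain >= 20]

    ref16 = _resolve_marker("16:0", {c: parsed[c] for c in keep_cols})
    if ref16:
        amounts16 = table[ref16].fillna(0.0).sum(axis=1)
        keep_mask = amounts16 > 0
    else:
        keep_mask = pd.Series(False, index=table.index)
    removed = (
        table.loc[~keep_mask, "core_id"].tolist()
        if "core_id" in table.columns
        else table.index[~keep_mask].tolist()
    )
    out = table.loc[keep_mask, [c for c in table.columns if c not in dropped_cols]].copy()

    all_markers = set(
        FUNGAL_MARKERS + BACTERIAL_MARKERS + GM_POS_MARKERS + GM_NEG_MARKERS
    )
    kept_parsed = {c: parsed[c] for c in keep_cols}
    coverage = {m: bool(_resolve_marker(m, kept_parsed)) for m in sorted(all_markers)}
    report = {
        "removed_cores": removed,
        "n_removed": len(removed),
        "dropped_columns": dropped_cols,
        "marker_coverage": coverage,
    }
    return out, report


def mole_percent(table: pd.DataFrame) -> pd.DataFrame:
    """Per-core relative mole percents: each core's lipid values scaled to sum
    to 100.  Raises on a core with zero total (cannot normalise)."""
    cols = lipid_columns(table)
    amounts = table[cols].fillna(0.0)
    totals = amounts.sum(axis=1)
    if np.any(totals <= 0):
        bad = table.index[totals <= 0].tolist()
        raise ValueError(f"cannot normalise core(s) with zero total amount: {bad}")
    out = table.copy()
    out[cols] = 100.0 * amounts.div(totals, axis=0)
    return out


def _marker_total(values: "pd.Series | dict", markers: tuple[str, ...]) -> float:
    values = pd.Series(values, dtype=float)
    parsed = {}
    for c in values.index:
        try:
            parsed[c] = parse_lipid(c)
        except ValueError:
            continue
    total = 0.0
    for m in markers:
        for c in _resolve_marker(m, parsed):
            v = values[c]
            if np.isfinite(v):
                total += float(v)
    return total


def fb_ratio(values: "pd.Series | dict") -> float:
    """Fungi-to-bacteria ratio of one core's mole fractions (or any positive
    rescaling of them — the ratio is scale-free).  Absent markers contribute
    zero; a zero bacterial (denominator) sum yields NaN, flagging the ratio
    as undefined rather than raising."""
    num = _marker_total(values, FUNGAL_MARKERS)
    den = _marker_total(values, BACTERIAL_MARKERS)
    return num / den if den > 0 else float("nan")


def marker_sums(values: "pd.Series | dict") -> tuple[float, float]:
    """(Gram-positive, Gram-negative) bacterial marker sums, on the scale of
    the input (mole fractions of the filtered profile in normal use)."""
    return (
        _marker_total(values, GM_POS_MARKERS),
        _marker_total(values, GM_NEG_MARKERS),
    )


def stress_ratio(values: "pd.Series | dict") -> float:
    """i15:0 / a15:0 — a coarse physiological stress indicator; NaN (flagged
    undefined) when a15:0 is absent or zero."""
    num = _marker_total(values, ("i15:0",))
    den = _marker_total(values, ("a15:0",))
    return num / den if den > 0 else float("nan")


def community_metrics(table: pd.DataFrame, filtered: bool = False) -> pd.DataFrame:
    """Per-core community metrics from a wide amounts table.

    Applies :func:`filter_cores` first unless ``filtered`` is set, then
    computes, per core: total lipid abundance (nmol, sum of retained
    amounts), fungi-to-bacteria ratio, Gram+ and Gram− marker sums (mole
    fractions) and the i15:0/a15:0 stress ratio.
    """
    if not filtered:
        table, _ = filter_cores(table)
    cols = lipid_columns(table)
    amounts = table[cols].fillna(0.0)
    abundance = amounts.sum(axis=1)
    fracs = amounts.div(abundance, axis=0)

    rows = []
    for idx in table.index:
        v = fracs.loc[idx]
        gp, gn = marker_sums(v)
        rows.append(
            {
                "abundance_nmol": float(abundance.loc[idx]),
                "fb_ratio": fb_ratio(v),
                "gm_pos": gp,
                "gm_neg": gn,
                "stress_ratio": stress_ratio(v),
            }
        )
    out = pd.DataFrame(rows, index=table.index)
    for meta in META_COLUMNS:
        if meta in table.columns:
            out.insert(0, meta, table[meta])
    return out


def plot_summary(values) -> tuple[float, float, int]:
    """(mean, standard error, n) over non-missing values; SE = sd/sqrt(n)
    with the sample (ddof=1) sd, NaN-flagged when n < 2."""
    v = np.asarray(pd.Series(values).dropna(), dtype=float)
    n = v.size
    if n == 0:
        return float("nan"), float("nan"), 0
    mean = float(np.mean(v))
    se = float(np.std(v, ddof=1) / np.sqrt(n)) if n >= 2 else float("nan")
    return mean, se, n


def summarize_metrics(metrics: pd.DataFrame) -> pd.DataFrame:
    """Plot-level mean ± 1 SE table of the per-core community metrics."""
    rows = {}
    for col in ("abundance_nmol", "fb_ratio", "gm_pos", "gm_neg", "stress_ratio"):
        if col in metrics.columns:
            mean, se, n = plot_summary(metrics[col])
            rows[col] = {"mean": mean, "se": se, "n": n}
    out = pd.DataFrame(rows).T
    out["n"] = out["n"].astype(int)
    out.index.name = "metric"
    return out


class PLFAMetrics(TransformerMixin, BaseEstimator):
    """Transformer from wide per-core lipid amount tables to community
    metrics; a stateless wrapper over :func:`filter_cores` and
    :func:`community_metrics` that composes with sklearn pipelines.

    After ``transform``, ``report_`` holds the core/column rejection report.
    """

    def fit(self, X: pd.DataFrame, y=None):
        lipid_columns(X)  # raises early on a malformed frame
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        filtered, self.report_ = filter_cores(X)
        return community_metrics(filtered, filtered=True)
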