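"""Occupation coding: crosswalks to ISEI / SIOPS / CAMSIS and phenotype transforms.

Occupational status scales attach a continuous score to an occupation code:
ISEI (socioeconomic index), SIOPS (Treiman prestige) and CAMSIS (social
interaction and stratification). Real crosswalk tables (e.g. SOC2000 ->
ISCO-88(COM) -> scores) are licensable external artifacts; this module
defines the delimited-text schema they plug into and ships a clearly
synthetic 12-code toy table for tests and documentation.

Crosswalk file schema: comma-separated with header
``occupation_code,isei,siops,camsis``; optional leading metadata lines
starting with ``#`` of the form ``# key: value`` (recognised keys:
``provenance`` and ``<scale>_range: low-high`` declaring score bounds).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, FormatError

logger = logging.getLogger("statusgen")

SCALES = ("isei", "siops", "camsis")


@dataclass
class CrosswalkTable:
    """Occupation-code -> status-score lookup.

    ``frame`` is indexed by occupation code (string) with one float column
    per scale; a scale absent from the file is marked unavailable rather
    than an error.
    """

    frame: pd.DataFrame
    provenance: str = "unknown"
    bounds: dict = field(default_factory=dict)

    @property
    def available(self) -> tuple:
        return tuple(s for s in SCALES if s in self.frame.columns)

    def __len__(self) -> int:
        return len(self.frame)

    def lookup(self, code: str):
        """Scores for one occupation code, or None if unmapped."""
        code = str(code)
        if code not in self.frame.index:
            return None
        row = self.frame.loc[code]
        return {s: float(row[s]) if pd.notna(row[s]) else np.nan for s in self.available}


@dataclass(frozen=True)
class OccupationRecord:
    person_id: object
    occupation_code: str
    observed_at: float  # orderable timestamp or wave index


@dataclass
class ScoringLog:
    """Counters surfaced to the run log: unmapped codes and recency ties."""

    unmapped: int = 0
    ties: int = 0


def load_crosswalk(path) -> CrosswalkTable:
    """Load and validate a crosswalk table from delimited text."""
    meta: dict = {}
    header_lines = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    df = pd.read_csv(path, skiprows=header_lines, dtype={"occupation_code": str})
    if "occupation_code" not in df.columns:
        raise FormatError("crosswalk is missing the occupation_code column")
    if df.empty:
        raise FormatError("crosswalk table is empty")
    dup = df["occupation_code"][df["occupation_code"].duplicated()]
    if not dup.empty:
        raise FormatError(f"duplicate occupation code(s): {sorted(dup.unique())}")
    present = [s for s in SCALES if s in df.columns]
    if not present:
        raise FormatError("crosswalk has no score column (isei/siops/camsis)")
    missing_scales = [s for s in SCALES if s not in df.columns]
    if missing_scales:
        logger.info("crosswalk %s: scale(s) unavailable: %s", path, missing_scales)
    frame = df.set_index("occupation_code")[present].astype(float)
    if frame.isna().all(axis=1).any():
        bad = frame.index[frame.isna().all(axis=1)].tolist()
        raise FormatError(f"rows with no score at all: {bad}")
    bounds = {}
    for s in present:
        key = f"{s}_range"
        if key in meta:
            lo, _, hi = meta[key].partition("-")
            bounds[s] = (float(lo), float(hi))
            col = frame[s].dropna()
            if ((col < bounds[s][0]) | (col > bounds[s][1])).any():
                raise FormatError(f"{s} scores outside declared range {bounds[s]}")
    return CrosswalkTable(
        frame=frame, provenance=meta.get("provenance", "unknown"), bounds=bounds
    )


def score_person(
    records: list,
    crosswalk: CrosswalkTable,
    log: ScoringLog | None = None,
) -> dict:
    """Score one person from their occupation records.

    The most recent record (largest ``observed_at``) wins; ties are broken
    by the last-listed record and counted in the log. An empty record list
    or an unmapped code yields missing scores, not an error.
    """
    missing = {s: np.nan for s in crosswalk.available}
    if not records:
        return missing
    best = records[0]
    tie = False
    for rec in records[1:]:
        if rec.observed_at > best.observed_at:
            best, tie = rec, False
        elif rec.observed_at == best.observed_at:
            best, tie = rec, True  # last-listed wins on ties
    if tie:
        if log is not None:
            log.ties += 1
        logger.info(
            "person %s: recency tie at %s, last-listed record used",
            best.person_id, best.observed_at,
        )
    scores = crosswalk.lookup(best.occupation_code)
    if scores is None:
        if log is not None:
            log.unmapped += 1
        return missing
    return scores


def score_table(
    occupations: pd.DataFrame,
    crosswalk: CrosswalkTable,
    log: ScoringLog | None = None,
) -> pd.DataFrame:
    """Score a long table (person_id, occupation_code, observed_at) to one
    row per person."""
    out = {}
    for pid, grp in occupations.groupby("person_id", sort=False):
        records = [
            OccupationRecord(pid, str(r.occupation_code), r.observed_at)
            for r in grp.itertuples()
        ]
        out[pid] = score_person(records, crosswalk, log)
    res = pd.DataFrame.from_dict(out, orient="index")
    res.index.name = "person_id"
    return res.reset_index()


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset.

    Non-missing entries are replaced by Phi^-1((rank - 3/8) / (n + 1/4));
    ties receive average ranks; missing values are preserved. The result is
    invariant under any strictly monotone transform of the input.
    """
    x = np.asarray(values, dtype=float)
    mask = ~np.isnan(x)
    n = int(mask.sum())
    if n == 0:
        raise DegenerateInputError("all values are missing")
    if n < 2:
        raise DegenerateInputError("need at least 2 non-missing values")
    ranks = stats.rankdata(x[mask], method="average")
    out = np.full_like(x, np.nan)
    out[mask] = stats.norm.ppf((ranks - 3.0 / 8.0) / (n + 0.25))
    return out


def toy_crosswalk() -> CrosswalkTable:
    """The bundled 12-code synthetic crosswalk (codes and scores invented)."""
    codes = [f"S{i:03d}" for i in range(1, 13)]
    frame = pd.DataFrame(
        {
            "isei": [16, 23, 30, 38, 43, 51, 56, 62, 70, 77, 85, 88],
            "siops": [13, 20, 28, 34, 40, 47, 52, 60, 64, 71, 75, 78],
            "camsis": [5, 14, 22, 31, 40, 49, 57, 66, 74, 83, 91, 99],
        },
        index=pd.Index(codes, name="occupation_code"),
        dtype=float,
    )
    return CrosswalkTable(
        frame=frame,
        provenance="synthetic-toy",
        bounds={"isei": (16, 90), "siops": (6, 78), "camsis": (1, 99)},
    )


def write_toy_crosswalk(path) -> None:
    """Write the synthetic toy crosswalk in the documented file schema."""
    cw = toy_crosswalk()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# provenance: synthetic-toy\n")
        for s, (lo, hi) in cw.bounds.items():
            fh.write(f"# {s}_range: {lo:g}-{hi:g}\n")
        cw.frame.reset_index().to_csv(fh, index=False)
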