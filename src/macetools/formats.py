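"""File formats: response CSVs in and score/fit-report CSVs out.

Response CSV layout: first column the person id, remaining columns item
ids (any order, case-insensitive, with or without a leading "m"). Two
cell conventions are supported:

* binary — cells 0 / 1 / empty (missing);
* age-annotated — cells hold semicolon-delimited age lists ("7;8;9"),
  empty meaning not endorsed; a bare list implies endorsement. Optional
  companion columns "<item>_ages" may carry the lists next to binary
  response columns instead.

Parsing mirrors the released scorer's purpose of catching common entry
errors: non-binary response values, age tokens outside 1-18, and age
lists attached to non-endorsed cells are each reported with row/column
coordinates and can be auto-corrected (value nulled, offending ages
dropped) under ``fix=True``. All writers use a stable column order and
fixed decimal formatting so outputs diff cleanly.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .instrument import SUBSCALE_ORDER, InstrumentDefinition
from .rasch import ResponseMatrix
from .fitstats import RaschCalibration

__all__ = ["ParseIssue", "parse_mace_csv", "write_responses", "write_scores",
           "write_fit_report", "write_chronology", "reproduce_published_calibration"]


@dataclass
class ParseIssue:
    row: object        # person id
    column: str
    kind: str          # non_binary_value | age_out_of_range | ages_on_unendorsed
    detail: str
    fixed: bool


def _norm_item(col: str):
    m = re.fullmatch(r"(?i)m?(\d+)", col.strip())
    return int(m.group(1)) if m else None


def parse_mace_csv(path, defn: InstrumentDefinition | None = None,
                   fix: bool = False):
    """Parse a response CSV; returns (ResponseMatrix, issues).

    Columns are resolved against the instrument's item ids when ``defn``
    is given (unresolvable response columns are fatal); otherwise every
    non-ages column after the first is treated as an item. Correctable
    entry errors are reported and, under ``fix``, nulled/dropped;
    without ``fix`` they raise.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError("response CSV needs a person-id column plus item columns")
    person_col = df.columns[0]
    issues: list[ParseIssue] = []

    item_cols: dict[int, str] = {}
    age_cols: dict[int, str] = {}
    for col in df.columns[1:]:
        m = re.fullmatch(r"(?i)(m?\d+)_ages", col.strip())
        if m:
            iid = _norm_item(m.group(1))
            age_cols[iid] = col
            continue
        iid = _norm_item(col)
        if iid is None or (defn is not None and iid not in defn.all_item_ids):
            raise ValueError(f"column {col!r} does not resolve to an instrument item")
        item_cols[iid] = col
    if defn is not None:
        missing = sorted(set(defn.all_item_ids) - set(item_cols))
        if missing:
            raise ValueError(f"response CSV lacks columns for items {missing}")

    items = sorted(item_cols)
    persons = df[person_col].tolist()
    values = np.full((len(persons), len(items)), np.nan)
    ages: dict = {}

    def parse_age_list(token: str, pid, colname):
        out = set()
        for part in token.split(";"):
            part = part.strip()
            if not part:
                continue
            try:
                a = int(part)
            except ValueError:
                a = None
            if a is None or not 1 <= a <= 18:
                issues.append(ParseIssue(pid, colname, "age_out_of_range",
                                         f"age token {part!r} outside 1-18", fix))
                if not fix:
                    raise ValueError(f"row {pid}, column {colname}: age token "
                                     f"{part!r} outside 1-18 (use fix=True to drop)")
                continue
            out.add(a)
        return out

    # convention sniff: a semicolon anywhere in the response columns marks
    # the inline age-annotated layout; otherwise cells are binary
    inline_ages = any(
        ";" in df.iloc[p][item_cols[iid]] for p in range(len(persons))
        for iid in items
    )

    for p, pid in enumerate(persons):
        for j, iid in enumerate(items):
            cell = df.iloc[p][item_cols[iid]].strip()
            if cell == "":
                continue
            if inline_ages and cell not in ("0", "1"):
                # age-annotated convention: the cell itself lists ages; a
                # bare "1" stays a plain endorsement ("1;" marks the
                # single-year list {1})
                aset = parse_age_list(cell, pid, item_cols[iid])
                if aset:
                    values[p, j] = 1.0
                    ages[(p, j)] = frozenset(aset)
                continue
            if cell in ("0", "1"):
                values[p, j] = float(cell)
            else:
                issues.append(ParseIssue(pid, item_cols[iid], "non_binary_value",
                                         f"value {cell!r} not in {{0,1,empty}}", fix))
                if not fix:
                    raise ValueError(f"row {pid}, column {item_cols[iid]}: "
                                     f"non-binary value {cell!r} (use fix=True to null)")
                values[p, j] = np.nan
        for iid, colname in age_cols.items():
            if iid not in item_cols:
                continue
            cell = df.iloc[p][colname].strip()
            if cell == "":
                continue
            j = items.index(iid)
            aset = parse_age_list(cell, pid, colname)
            if not aset:
                continue
            if values[p, j] != 1.0:
                issues.append(ParseIssue(pid, colname, "ages_on_unendorsed",
                                         "age list on a non-endorsed cell", fix))
                if not fix:
                    raise ValueError(f"row {pid}, column {colname}: age list on a "
                                     "non-endorsed cell (use fix=True to drop)")
                continue
            ages[(p, j)] = frozenset(aset)

    rm = ResponseMatrix(persons, items, values, ages or None)
    return rm, issues


def write_responses(path, rm: ResponseMatrix, inline_ages: bool = False):
    """Write a ResponseMatrix back to CSV (lossless round-trip)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        header = ["person"] + [f"m{i}" for i in rm.items]
        if not inline_ages and rm.ages:
            header += [f"m{i}_ages" for i in rm.items]
        w.writerow(header)
        for p, pid in enumerate(rm.persons):
            row = [pid]
            for j in range(rm.n_items):
                v = rm.values[p, j]
                if np.isnan(v):
                    row.append("")
                elif inline_ages:
                    aset = rm.ages.get((p, j)) if rm.ages else None
                    if aset:
                        token = ";".join(str(a) for a in sorted(aset))
                        # "1;" keeps the single-year list {1} distinct from
                        # a plain endorsement
                        row.append("1;" if token == "1" else token)
                    else:
                        row.append("1" if v == 1 else "0")
                else:
                    row.append(str(int(v)))
            if not inline_ages and rm.ages:
                for j in range(rm.n_items):
                    aset = rm.ages.get((p, j))
                    row.append(";".join(str(a) for a in sorted(aset)) if aset else "")
            w.writerow(row)


def write_scores(path, score_sets, defn: InstrumentDefinition):
    """One row per person: 10 severities, 10 flags, multiplicity, total,
    and 18 per-year totals when chronology was scored."""
    names = [n for n in SUBSCALE_ORDER if n in defn.subscales]
    lo, hi = defn.age_range
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        header = (["person"]
                  + [f"{n}_severity" for n in names]
                  + [f"{n}_exposed" for n in names]
                  + ["multiplicity", "total_severity"]
                  + [f"severity_age_{a}" for a in range(lo, hi + 1)])
        w.writerow(header)
        for s in score_sets:
            row = [s.person]
            for n in names:
                sev = s.subscale_scores[n].severity
                row.append("" if np.isnan(sev) else f"{sev:.2f}")
            for n in names:
                e = s.subscale_scores[n].exposed
                row.append("" if e is None else int(e))
            row += [s.multiplicity, f"{s.total_severity:.2f}"]
            if s.chronology_total is not None:
                row += [f"{v:.2f}" for v in s.chronology_total]
            else:
                row += [""] * (hi - lo + 1)
            w.writerow(row)


def write_chronology(path, score_sets, defn: InstrumentDefinition):
    """Long-format chronology: person, age, subscale, severity."""
    names = [n for n in SUBSCALE_ORDER if n in defn.subscales]
    lo, hi = defn.age_range
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["person", "age", "subscale", "severity"])
        for s in score_sets:
            if s.chronology is None:
                continue
            for row_i, age in enumerate(range(lo, hi + 1)):
                for col, n in enumerate(names):
                    v = s.chronology[row_i, col]
                    w.writerow([s.person, age, n,
                                "" if np.isnan(v) else f"{v:.2f}"])


def write_fit_report(path, calib: RaschCalibration, data: ResponseMatrix):
    """Fit report mirroring the published table layout:
    item_id, observations, %yes, difficulty (se), outfit_msq, infit_msq."""
    obs = data.item_observation_counts()
    pct = 100.0 * np.nansum(data.values, axis=0) / np.maximum(obs, 1)
    fit_by_item = {f.item_id: f for f in calib.fits}
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["item_id", "observations", "pct_yes", "difficulty", "se",
                    "outfit_msq", "infit_msq"])
        for j, item in enumerate(data.items):
            bidx = calib.bank.item_ids.index(item)
            se = (calib.bank.difficulty_se[bidx]
                  if calib.bank.difficulty_se is not None else np.nan)
            f = fit_by_item[item]
            w.writerow([item, int(obs[j]), f"{pct[j]:.1f}",
                        f"{calib.bank.difficulty[bidx]:.2f}",
                        "" if np.isnan(se) else f"{se:.2f}",
                        f"{f.outfit_msq:.2f}", f"{f.infit_msq:.2f}"])


def reproduce_published_calibration(responses_csv, defn: InstrumentDefinition,
                                    age_column: str | None = None):
    """Recalibrate every subscale from a deposited psychometrics CSV.

    Given person-level item responses in the study's layout (plus an
    optional age covariate column for the Andersen partition), runs the
    conditional-ML calibration, fit statistics and Andersen test per
    subscale and returns a tidy DataFrame for comparison against the
    published tables.
    """
    from .fitstats import calibrate, median_split

    df = pd.read_csv(responses_csv)
    rm, _ = parse_mace_csv(responses_csv, defn=None, fix=True)
    partition = None
    if age_column is not None:
        partition = median_split(df[age_column].to_numpy())
    rows = []
    for name in SUBSCALE_ORDER:
        if name not in defn.subscales:
            continue
        sub = defn.subscales[name]
        cols = [i for i in sub.item_ids if i in rm.items]
        sel = rm.subset_items(cols)
        vals = sel.values.copy()
        for item in sub.reverse_ids:
            if item in sel.items:
                j = sel.items.index(item)
                vals[:, j] = 1.0 - vals[:, j]
        flipped = ResponseMatrix(sel.persons, sel.items, vals)
        keep = flipped.observed_counts() == len(cols)
        flipped = flipped.drop_persons(keep)
        part = partition[keep] if partition is not None else None
        calib = calibrate(flipped, partition=part)
        for f in calib.fits:
            j = calib.bank.item_ids.index(f.item_id)
            rows.append({
                "subscale": name, "item_id": f.item_id,
                "difficulty": calib.bank.difficulty[j],
                "se": calib.bank.difficulty_se[j],
                "outfit_msq": f.outfit_msq, "infit_msq": f.infit_msq,
                "andersen_lr": calib.andersen.lr_statistic if calib.andersen else np.nan,
                "andersen_df": calib.andersen.df if calib.andersen else np.nan,
                "andersen_p": calib.andersen.p_value if calib.andersen else np.nan,
            })
    return pd.DataFrame(rows)
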