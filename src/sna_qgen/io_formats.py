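"""Delimited-text I/O, schema validation and directly derived performance traits.

All files are comma-separated UTF-8 with a header row and '.' decimal mark.
Missing values are empty fields.  Schemas:

* ``fights.csv``       — pen_id, animal_a, animal_b, duration_s
* ``pedigree.csv``     — animal, sire, dam        (unknown parent: 0 or empty)
* ``animals.csv``      — animal, pen_id, line, sex, batch, mixing_weight_kg
* ``performance.csv``  — animal, TDG, LDG, DFI, FE, FBW, HCW, BF, LD
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: performance trait columns, in canonical order
PERFORMANCE_TRAITS = ["TDG", "LDG", "DFI", "FE", "FBW", "HCW", "BF", "LD"]

SEX_LEVELS = ("female", "castrate")

FLOAT_FMT = "%.12g"  # 12 significant digits: round-trip stable for our tables


class ValidationError(ValueError):
    """A malformed input row; the message names the file, row and offence."""


@dataclass(frozen=True)
class DyadicFightRecord:
    """One observed reciprocal fight aggregate between two penmates.

    ``duration`` is the total reciprocal-fight duration in seconds; it is the
    raw material of the network edge weights.  Several records for the same
    unordered dyad may coexist (summed later during aggregation).
    """

    pen_id: str
    animal_a: str
    animal_b: str
    duration: float

    def __post_init__(self) -> None:
        if self.animal_a == self.animal_b:
            raise ValidationError(
                f"self-pair: animal {self.animal_a!r} fights itself in pen {self.pen_id!r}"
            )
        if not np.isfinite(self.duration) or self.duration <= 0:
            raise ValidationError(
                f"non-positive duration {self.duration!r} for dyad "
                f"({self.animal_a!r}, {self.animal_b!r}) in pen {self.pen_id!r}"
            )

    @property
    def dyad(self) -> frozenset:
        return frozenset((self.animal_a, self.animal_b))


@dataclass(frozen=True)
class PenRoster:
    """Full membership of one single-sex pen formed at mixing."""

    pen_id: str
    members: tuple
    sex: str
    batch: str

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValidationError(f"duplicate members in pen {self.pen_id!r}")
        if self.sex not in SEX_LEVELS:
            raise ValidationError(
                f"pen {self.pen_id!r}: sex {self.sex!r} not in {SEX_LEVELS}"
            )


def read_animals(path) -> pd.DataFrame:
    """Read per-animal metadata (pen, line, sex, batch, mixing weight).

    Returns a DataFrame indexed by animal id (string).  Raises
    :class:`ValidationError` on duplicate animals, unknown sex levels or
    non-positive mixing weights.
    """
    df = pd.read_csv(path, dtype={"animal": str, "pen_id": str, "line": str,
                                  "sex": str, "batch": str})
    required = {"animal", "pen_id", "line", "sex", "batch", "mixing_weight_kg"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    if df["animal"].duplicated().any():
        dup = df.loc[df["animal"].duplicated(), "animal"].iloc[0]
        raise ValidationError(f"{path}: duplicate animal {dup!r}")
    bad_sex = ~df["sex"].isin(SEX_LEVELS)
    if bad_sex.any():
        row = int(np.flatnonzero(bad_sex)[0])
        raise ValidationError(
            f"{path} row {row + 2}: sex {df['sex'].iloc[row]!r} not in {SEX_LEVELS}"
        )
    w = pd.to_numeric(df["mixing_weight_kg"], errors="coerce")
    bad_w = ~(w > 0)
    if bad_w.any():
        row = int(np.flatnonzero(bad_w)[0])
        raise ValidationError(
            f"{path} row {row + 2}: mixing_weight_kg must be positive, "
            f"got {df['mixing_weight_kg'].iloc[row]!r}"
        )
    df = df.copy()
    df["mixing_weight_kg"] = w
    return df.set_index("animal")


def rosters_from_animals(animals: pd.DataFrame) -> dict:
    """Group animal metadata into :class:`PenRoster` objects keyed by pen id.

    Enforces single-sex pens and batch uniformity within pen.
    """
    rosters = {}
    for pen_id, grp in animals.groupby("pen_id", sort=True):
        sexes = grp["sex"].unique()
        if len(sexes) != 1:
            raise ValidationError(f"pen {pen_id!r} mixes sexes {sorted(sexes)}")
        batches = grp["batch"].unique()
        if len(batches) != 1:
            raise ValidationError(f"pen {pen_id!r} spans batches {sorted(batches)}")
        rosters[pen_id] = PenRoster(
            pen_id=pen_id,
            members=tuple(grp.index),
            sex=sexes[0],
            batch=batches[0],
        )
    return rosters


def read_fight_records(path, rosters: dict) -> list:
    """Read and validate dyadic fight records against pen rosters.

    Row order is preserved; repeated rows for the same unordered dyad are
    allowed (they are summed during network aggregation downstream).
    """
    df = pd.read_csv(path, dtype={"pen_id": str, "animal_a": str, "animal_b": str})
    required = {"pen_id", "animal_a", "animal_b", "duration_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    records = []
    member_sets = {pid: set(r.members) for pid, r in rosters.items()}
    for i, row in enumerate(df.itertuples(index=False)):
        rowno = i + 2  # header is row 1
        if row.pen_id not in member_sets:
            raise ValidationError(f"{path} row {rowno}: unknown pen {row.pen_id!r}")
        members = member_sets[row.pen_id]
        for animal in (row.animal_a, row.animal_b):
            if animal not in members:
                raise ValidationError(
                    f"{path} row {rowno}: animal {animal!r} not in roster of pen "
                    f"{row.pen_id!r}"
                )
        try:
            duration = float(row.duration_s)
        except (TypeError, ValueError):
            raise ValidationError(
                f"{path} row {rowno}: non-numeric duration {row.duration_s!r}"
            ) from None
        try:
            rec = DyadicFightRecord(row.pen_id, row.animal_a, row.animal_b, duration)
        except ValidationError as exc:
            raise ValidationError(f"{path} row {rowno}: {exc}") from None
        records.append(rec)
    return records


def read_performance(path) -> pd.DataFrame:
    """Read per-animal performance phenotypes; empty fields become NaN."""
    df = pd.read_csv(path, dtype={"animal": str})
    if "animal" not in df.columns:
        raise ValidationError(f"{path}: missing column 'animal'")
    if df["animal"].duplicated().any():
        dup = df.loc[df["animal"].duplicated(), "animal"].iloc[0]
        raise ValidationError(f"{path}: duplicate animal {dup!r}")
    for col in df.columns:
        if col == "animal":
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.isfinite(df[col].notna()) & df[col].notna() & vals.isna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"{path} row {row + 2}: non-numeric value {df[col].iloc[row]!r} "
                f"in column {col}"
            )
        df[col] = vals
    return df.set_index("animal")


def derive_feed_efficiency(
    perf: pd.DataFrame,
    dfi_basis: str = "g_per_d",
    recompute: bool = False,
) -> pd.DataFrame:
    """Populate FE = TDG / DFI on a consistent unit basis.

    TDG is recorded in g/d.  ``dfi_basis`` declares the unit DFI was recorded
    in: ``"g_per_d"`` (default — FE is the dimensionless gain:feed ratio) or
    ``"kg_per_d"`` (DFI converted to g/d before dividing).  Existing FE values
    are kept unless ``recompute`` is set.  Rows where DFI is missing or zero
    keep FE missing, with a logged warning.
    """
    if dfi_basis not in ("g_per_d", "kg_per_d"):
        raise ValueError(f"unknown dfi_basis {dfi_basis!r}")
    out = perf.copy()
    if "FE" not in out.columns:
        out["FE"] = np.nan
    dfi = out["DFI"] * (1000.0 if dfi_basis == "kg_per_d" else 1.0)
    computable = out["TDG"].notna() & dfi.notna() & (dfi != 0)
    target = computable if recompute else (computable & out["FE"].isna())
    out.loc[target, "FE"] = out.loc[target, "TDG"] / dfi[target]
    skipped = out["TDG"].notna() & ~computable & out["FE"].isna()
    if skipped.any():
        logger.warning(
            "FE left missing for %d animals with missing/zero DFI (e.g. %s)",
            int(skipped.sum()), out.index[skipped][0],
        )
    return out


# ---------------------------------------------------------------------------
# pedigree reading (PedigreeTable lives in pedigree_kinship)


def read_pedigree(path):
    """Read a three-column pedigree and return a sorted :class:`PedigreeTable`.

    Unknown parents are coded ``0`` or left empty.  Animals are recoded to
    consecutive 1-based integers with parents preceding offspring; original
    labels are retained.  Cycles and duplicate animal rows raise
    :class:`ValidationError`.
    """
    from .pedigree_kinship import PedigreeTable  # local import avoids cycle

    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"animal", "sire", "dam"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    if df["animal"].duplicated().any():
        dup = df.loc[df["animal"].duplicated(), "animal"].iloc[0]
        raise ValidationError(f"{path}: duplicated animal row {dup!r}")
    try:
        return PedigreeTable.from_records(
            df["animal"].tolist(), df["sire"].tolist(), df["dam"].tolist()
        )
    except ValueError as exc:
        raise ValidationError(f"{path}: {exc}") from None


# ---------------------------------------------------------------------------
# result-table writing


def write_results_tables(summaries: dict, path_prefix: str) -> dict:
    """Write the result tables as CSV files under ``path_prefix``.

    ``summaries`` may contain any of the keys ``h2`` (per-trait variance
    ratios), ``rg_sna`` (network-trait genetic-correlation pairs),
    ``rg_sna_perf`` (network x performance pairs) and ``rp_spearman``
    (phenotypic rank-correlation matrix), each a DataFrame as produced by
    :mod:`sna_qgen.posterior_summary`.  Empty frames yield header-only files.
    Returns the mapping of table key to written path.
    """
    import os

    os.makedirs(os.path.dirname(path_prefix) or ".", exist_ok=True)
    written = {}
    names = {"h2": "h2_table.csv", "rg_sna": "rg_sna.csv",
             "rg_sna_perf": "rg_sna_perf.csv", "rp_spearman": "rp_spearman.csv"}
    for key, fname in names.items():
        if key not in summaries:
            continue
        out = f"{path_prefix}{fname}"
        df = summaries[key]
        if key == "rp_spearman":
            df.to_csv(out, float_format=FLOAT_FMT)
        else:
            df.to_csv(out, index=False, float_format=FLOAT_FMT)
        written[key] = out
    return written


def write_chain(chain_df: pd.DataFrame, path) -> None:
    """Write one thinned MCMC chain (one row per saved draw) as CSV."""
    chain_df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_chain(path) -> pd.DataFrame:
    return pd.read_csv(path)
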