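"""Assembly of pest x insecticide time-to-resistance records.

Each record tracks one herbivore-insecticide interaction from the year the
insecticide first became available to the pest (the evolutionary start) to
either the earliest documented resistance report (event = 1) or the end of
observation (event = 0, right-censored at the censor year, 2020 by default).

Two start-time conventions are supported:

``all_in``
    The start is the insecticide's generic first-registration year,
    regardless of crop.
``top_crops``
    The start is the earliest crop-specific registration year over the crop
    genera the pest actually uses.  When that year postdates a documented
    resistance report (registration ledgers only begin with the regulatory
    record, while resistance can be older), the generic year is used as a
    fallback and the record is tagged ``generic_fallback``.  Records whose
    resistance report precedes every registration year of any kind are
    excluded — a negative duration is a data error, never an observation.

The module also builds the fixed-effect design for the hazard models: diet
breadth and documentation intensity are log-transformed; diet breadth,
documentation and voltinism are mean-centered and scaled to unit range
(max - min = 1); the similarity index is left on its native [0, 1] scale;
squared terms are added for diet breadth, similarity and voltinism.  The
transform constants are stored so that prediction-time data can be placed on
exactly the training scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CENSOR_YEAR",
    "RegistrationLedger",
    "InteractionRecord",
    "TransformConstants",
    "resolve_start_year",
    "build_record",
    "assemble_records",
    "transform_covariates",
    "apply_transform",
    "dataset_summary",
    "load_deposited",
]

CENSOR_YEAR = 2020

#: design-matrix column names used by every engine
FIXED_EFFECT_COLUMNS = [
    "x_diet", "x_diet2", "x_sim", "x_sim2", "x_volt", "x_volt2", "x_doc", "x_haplo",
]


class MissingRegistrationError(KeyError):
    """No registration year of any kind exists for an insecticide."""


@dataclass(frozen=True)
class RegistrationLedger:
    """Registration years for one insecticide.

    generic_year
        Earliest registration for any crop.
    crop_years
        Crop genus -> earliest crop-specific registration year (may be
        empty; it is unused in ``all_in`` mode).
    """

    insecticide_id: str
    generic_year: int | None
    crop_years: Mapping[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class InteractionRecord:
    """One pest x insecticide time-to-event row."""

    pest_id: str
    insecticide_id: str
    start_year: int
    stop_year: int
    event: int
    start_source: str  # crop_specific | generic_fallback | generic

    @property
    def duration(self) -> int:
        return self.stop_year - self.start_year


def resolve_start_year(
    host_genera: Iterable[str],
    ledger: RegistrationLedger,
    mode: str = "all_in",
    resistance_year: int | None = None,
) -> tuple[int, str]:
    """Evolutionary start year and its provenance for one interaction.

    In ``top_crops`` mode the start is the minimum crop-specific
    registration year over the pest's host crop genera; if that minimum is
    later than a documented resistance year the generic year is used instead
    (``generic_fallback``).  ``all_in`` mode always uses the generic year.
    """
    if mode not in ("all_in", "top_crops"):
        raise ValueError(f"unknown mode {mode!r}")
    generic = ledger.generic_year
    if mode == "all_in":
        if generic is None:
            raise MissingRegistrationError(ledger.insecticide_id)
        return int(generic), "generic"

    years = [ledger.crop_years[g] for g in set(host_genera) if g in ledger.crop_years]
    if not years:
        if generic is None:
            raise MissingRegistrationError(ledger.insecticide_id)
        return int(generic), "generic"
    crop_year = int(min(years))
    if resistance_year is not None and crop_year > resistance_year and generic is not None:
        return int(generic), "generic_fallback"
    return crop_year, "crop_specific"


def build_record(
    pest_id: str,
    insecticide_id: str,
    start_year: int,
    start_source: str,
    resistance_year: int | None,
    censor_year: int = CENSOR_YEAR,
) -> InteractionRecord | None:
    """One interaction record, or ``None`` for an excluded (pre-start) report.

    A resistance report earlier than the start year even after the generic
    fallback cannot be represented as a non-negative duration and is
    excluded.  Resistance in the registration year itself yields duration 0
    and is kept (the Cox engine's tie policy handles it).
    """
    if resistance_year is None:
        return InteractionRecord(pest_id, insecticide_id, int(start_year), int(censor_year), 0, start_source)
    if resistance_year < start_year:
        return None
    return InteractionRecord(pest_id, insecticide_id, int(start_year), int(resistance_year), 1, start_source)


def assemble_records(
    hosts: pd.DataFrame,
    ledgers: Mapping[str, RegistrationLedger],
    reports: pd.DataFrame,
    mode: str = "all_in",
    censor_year: int = CENSOR_YEAR,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build every pest x insecticide record and an exclusion ledger.

    Parameters
    ----------
    hosts
        Columns ``pest_id, crop_genus`` (host crop genera per pest; genera
        may repeat).
    ledgers
        insecticide_id -> :class:`RegistrationLedger`.
    reports
        Columns ``pest_id, insecticide_id, first_resistance_year`` (earliest
        documented resistance per pair; pairs absent here are censored).

    Returns
    -------
    (records, exclusions)
        ``records`` columns: pest_id, insecticide_id, start_year, stop_year,
        duration, event, start_source.  ``exclusions`` columns: pest_id,
        insecticide_id, reason.
    """
    host_sets = hosts.groupby("pest_id")["crop_genus"].agg(set).to_dict()
    report_map = {
        (r.pest_id, r.insecticide_id): int(r.first_resistance_year)
        for r in reports.itertuples(index=False)
        if not pd.isna(r.first_resistance_year)
    }
    rows, excl = [], []
    for pest_id in sorted(host_sets):
        for ins_id in sorted(ledgers):
            res_year = report_map.get((pest_id, ins_id))
            try:
                start, source = resolve_start_year(host_sets[pest_id], ledgers[ins_id], mode, res_year)
            except MissingRegistrationError:
                excl.append({"pest_id": pest_id, "insecticide_id": ins_id, "reason": "no_registration_year"})
                continue
            rec = build_record(pest_id, ins_id, start, source, res_year, censor_year)
            if rec is None:
                excl.append(
                    {"pest_id": pest_id, "insecticide_id": ins_id, "reason": "resistance_precedes_registration"}
                )
                continue
            rows.append(
                {
                    "pest_id": rec.pest_id,
                    "insecticide_id": rec.insecticide_id,
                    "start_year": rec.start_year,
                    "stop_year": rec.stop_year,
                    "duration": rec.duration,
                    "event": rec.event,
                    "start_source": rec.start_source,
                }
            )
    records = pd.DataFrame(
        rows,
        columns=["pest_id", "insecticide_id", "start_year", "stop_year", "duration", "event", "start_source"],
    )
    exclusions = pd.DataFrame(excl, columns=["pest_id", "insecticide_id", "reason"])
    return records, exclusions


@dataclass(frozen=True)
class TransformConstants:
    """Per-column transform constants (applied as log? -> center -> /range)."""

    columns: Mapping[str, Mapping[str, float]]  # name -> {log, mean, min, max}

    def as_dict(self) -> dict:
        return {k: dict(v) for k, v in self.columns.items()}


def _scale_column(v: np.ndarray, log: bool, const: Mapping[str, float] | None):
    x = np.log(v) if log else np.asarray(v, dtype=float)
    if const is None:
        lo, hi, mu = float(x.min()), float(x.max()), float(x.mean())
        if hi == lo:
            raise ValueError("constant column cannot be range-scaled")
        const = {"log": float(log), "mean": mu, "min": lo, "max": hi}
    return (x - const["mean"]) / (const["max"] - const["min"]), const


def transform_covariates(
    df: pd.DataFrame,
    constants: TransformConstants | None = None,
    carry: Sequence[str] = ("pest_id", "insecticide_id", "family", "moa_class", "duration", "event"),
) -> tuple[pd.DataFrame, TransformConstants]:
    """Build the fixed-effect design from raw covariates.

    ``df`` must contain ``diet_breadth`` (host-genus count, >= 1),
    ``documentation`` (citation count; a +1 offset guards log 0),
    ``voltinism`` (generations/yr), ``similarity`` (in [0, 1]) and
    ``ploidy`` ("diplodiploid"/"haplodiploid").  Diet breadth and
    documentation are logged; those two plus voltinism are mean-centered and
    scaled to unit range; similarity passes through untouched; squares are
    appended for diet, similarity and voltinism (squares computed after
    transformation).  Pass stored ``constants`` to place new data on the
    training scale.
    """
    consts = dict(constants.columns) if constants is not None else {}
    out = pd.DataFrame(index=df.index)

    x, c = _scale_column(df["diet_breadth"].to_numpy(float), True, consts.get("diet_breadth"))
    out["x_diet"], consts["diet_breadth"] = x, c
    x, c = _scale_column(df["documentation"].to_numpy(float) + 1.0, True, consts.get("documentation"))
    out["x_doc"], consts["documentation"] = x, c
    x, c = _scale_column(df["voltinism"].to_numpy(float), False, consts.get("voltinism"))
    out["x_volt"], consts["voltinism"] = x, c

    sim = df["similarity"].to_numpy(float)
    if sim.min() < 0 or sim.max() > 1:
        raise ValueError("similarity must lie in [0, 1]")
    out["x_sim"] = sim
    out["x_haplo"] = (df["ploidy"] == "haplodiploid").astype(float)
    out["x_diet2"] = out["x_diet"] ** 2
    out["x_sim2"] = out["x_sim"] ** 2
    out["x_volt2"] = out["x_volt"] ** 2
    out = out[FIXED_EFFECT_COLUMNS]
    for col in carry:
        if col in df.columns:
            out[col] = df[col].to_numpy()
    return out, TransformConstants(consts)


def apply_transform(df: pd.DataFrame, constants: TransformConstants, **kw) -> pd.DataFrame:
    """Transform new raw covariates with stored training constants."""
    design, _ = transform_covariates(df, constants=constants, **kw)
    return design


def dataset_summary(records: pd.DataFrame, exclusions: pd.DataFrame | None = None) -> dict:
    """Event / censoring composition of an assembled dataset."""
    n_event = int((records["event"] == 1).sum())
    n_cens = int((records["event"] == 0).sum())
    by_source = (
        records.groupby("start_source")["event"].agg(["count", "sum"]).to_dict("index")
        if "start_source" in records.columns
        else {}
    )
    return {
        "n_event": n_event,
        "n_censored": n_cens,
        "n_total": n_event + n_cens,
        "n_excluded": 0 if exclusions is None else int(len(exclusions)),
        "by_start_source": {
            k: {"n": int(v["count"]), "n_event": int(v["sum"])} for k, v in by_source.items()
        },
    }


# -- deposited-data reader ---------------------------------------------------

_DEPOSITED_ALIASES = {
    "pest_id": ["pest_id", "species", "herbivore", "pest"],
    "insecticide_id": ["insecticide_id", "insecticide", "pesticide"],
    "duration": ["duration", "time", "years", "surv_time"],
    "event": ["event", "status", "resistance", "resisted"],
    "similarity": ["similarity", "sim", "max_sim", "tanimoto"],
    "diet_breadth": ["diet_breadth", "host_breadth", "n_host_genera", "hosts"],
    "voltinism": ["voltinism", "volt", "generations"],
    "documentation": ["documentation", "citations", "pubmed", "doc"],
    "ploidy": ["ploidy"],
    "family": ["family"],
    "moa_class": ["moa_class", "moa", "mode_of_action", "irac"],
}


def load_deposited(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a deposited interaction CSV, normalising column names.

    Published interaction tables ship one row per pest x insecticide with a
    duration, an event flag and the covariates; header spellings vary, so
    common aliases are recognised and an explicit ``column_map``
    (canonical -> actual) overrides them.  Raises ``FileNotFoundError`` if
    the file is absent and ``KeyError`` if a required column cannot be
    located.
    """
    df = pd.read_csv(path)
    lower = {c.lower(): c for c in df.columns}
    rename: dict[str, str] = {}
    for canon, aliases in _DEPOSITED_ALIASES.items():
        if column_map and canon in column_map:
            rename[column_map[canon]] = canon
            continue
        for a in aliases:
            if a in lower:
                rename[lower[a]] = canon
                break
    out = df.rename(columns=rename)
    for required in ("duration", "event"):
        if required not in out.columns:
            raise KeyError(f"could not locate a {required!r} column in {path}")
    return out
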