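"""Patient records, tabular I/O and the synthetic ARDS cohort generator.

A :class:`PatientRecord` bundles everything one hazard report needs:
respiratory mechanics, an ambient blood-gas panel and a pure-oxygen panel
(for true shunt), plus an optional compliance interface pair.  Records can
be read from JSON/YAML (nested, mirroring the model structure) or from a
flat CSV table whose columns are listed in :data:`CSV_COLUMNS`.

The synthetic cohort generator draws clinically plausible ARDS-range
inputs and constructs the blood-gas panels *backwards* from chosen shunt
and low-V/Q fractions, so every generated record is coherent by
construction: CvO2 <= CaO2 <= CcO2, admixture >= true shunt, and the lung
partition (baby lung + low V/Q + shunt) sums below 1.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Any, Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .baby_lung_power import PatientMechanics
from .core_mechanics import VentilationCycle
from .exceptions import SchemaError
from .gas_exchange import BloodGasPanel, HB_O2_CAPACITY, O2_SOLUBILITY, alveolar_po2
from .hazard_index import HazardReport
from .interface_amplification import InterfacePair

__all__ = [
    "PatientRecord",
    "CSV_COLUMNS",
    "read_patient_table",
    "write_report",
    "read_reports",
    "generate_synthetic_cohort",
    "cohort_to_frame",
]

#: Fixed column schema of the flat CSV patient table (order is the written order).
CSV_COLUMNS: List[str] = [
    "identifier",
    "c_obs",          # mL/cmH2O
    "c_pred",         # mL/cmH2O
    "peep",           # cmH2O
    "driving_pressure",  # cmH2O
    "tidal_volume",   # L
    "frequency",      # breaths/min
    "c1",             # mL/cmH2O (interface pair, optional)
    "c2",
    "hb",             # g/dL
    "paco2",          # mmHg
    "fio2",           # ambient inspired O2 fraction
    "sao2", "pao2", "svo2", "pvo2",              # ambient panel
    "sao2_o2", "pao2_o2", "svo2_o2", "pvo2_o2",  # pure-oxygen panel (fio2 = 1)
]

_REPORT_FIELDS = [
    "stress_multiplier",
    "strain_multiplier",
    "surface_energy_ratio",
    "baby_lung_fraction",
    "interface_fraction",
    "specific_power",
    "total_power",
    "interface_fraction_of_baby_lung",
]


class PatientRecord(BaseModel):
    """One patient's complete model input; unknown fields are rejected."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    identifier: str
    mechanics: PatientMechanics
    ambient_panel: BloodGasPanel
    pure_o2_panel: BloodGasPanel
    interface_pair: Optional[InterfacePair] = None


def _record_from_flat(row: Dict[str, Any]) -> PatientRecord:
    mech = PatientMechanics(
        c_obs=row["c_obs"],
        c_pred=row["c_pred"],
        cycle=VentilationCycle(
            peep=row["peep"],
            driving_pressure=row["driving_pressure"],
            tidal_volume=row["tidal_volume"],
            frequency=row["frequency"],
        ),
    )
    ambient = BloodGasPanel(
        hb=row["hb"], paco2=row["paco2"], fio2=row["fio2"],
        sao2=row["sao2"], pao2=row["pao2"], svo2=row["svo2"], pvo2=row["pvo2"],
    )
    pure = BloodGasPanel(
        hb=row["hb"], paco2=row["paco2"], fio2=1.0,
        sao2=row["sao2_o2"], pao2=row["pao2_o2"],
        svo2=row["svo2_o2"], pvo2=row["pvo2_o2"],
    )
    pair = None
    c1, c2 = row.get("c1"), row.get("c2")
    if c1 is not None and c2 is not None and not (pd.isna(c1) or pd.isna(c2)):
        pair = InterfacePair(c1=c1, c2=c2)
    return PatientRecord(
        identifier=str(row["identifier"]),
        mechanics=mech,
        ambient_panel=ambient,
        pure_o2_panel=pure,
        interface_pair=pair,
    )


def read_patient_table(
    path: Union[str, Path], format: Optional[str] = None
) -> List[PatientRecord]:
    """Read and validate a patient table (csv, json or yaml).

    CSV files must carry the :data:`CSV_COLUMNS` header (c1/c2 may be
    blank); JSON/YAML files hold a list of nested record objects.  Row-level
    validation errors are collected and raised together as one
    :class:`~lungstress.exceptions.SchemaError` naming each failing row.
    An empty table returns an empty list with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"patient table not found: {path}")
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt in ("yml",):
        fmt = "yaml"
    if fmt == "csv":
        if path.stat().st_size == 0:
            warnings.warn(f"empty patient table: {path}", UserWarning, stacklevel=2)
            return []
        frame = pd.read_csv(path)
        missing = [c for c in CSV_COLUMNS if c not in frame.columns and c not in ("c1", "c2")]
        if missing:
            raise SchemaError(f"patient table {path} is missing required columns: {missing}")
        rows = frame.to_dict(orient="records")
        builders = [lambda r=r: _record_from_flat(r) for r in rows]
    elif fmt in ("json", "yaml"):
        with open(path) as fh:
            data = json.load(fh) if fmt == "json" else yaml.safe_load(fh)
        if not data:
            warnings.warn(f"empty patient table: {path}", UserWarning, stacklevel=2)
            return []
        if not isinstance(data, list):
            raise SchemaError(f"{path}: expected a list of patient records")
        builders = [lambda r=r: PatientRecord.model_validate(r) for r in data]
    else:
        raise SchemaError(f"unsupported patient-table format: {fmt!r}")

    records: List[PatientRecord] = []
    errors: List[str] = []
    for i, build in enumerate(builders):
        try:
            records.append(build())
        except (ValidationError, ValueError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise SchemaError(
            f"{len(errors)} invalid row(s) in {path}:\n" + "\n".join(errors)
        )
    return records


def write_report(
    reports: Sequence[HazardReport], path: Union[str, Path], format: Optional[str] = None
) -> None:
    """Write hazard reports to JSON (full, including provenance) or CSV (flat).

    Round-trips losslessly through :func:`read_reports`; CSV column order is
    fixed (identifier-free reports are written in input order).
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "json":
        payload = [r.model_dump() for r in reports]
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif fmt == "csv":
        frame = pd.DataFrame(
            [
                {**{f: getattr(r, f) for f in _REPORT_FIELDS},
                 "provenance": json.dumps(r.provenance, sort_keys=True)}
                for r in reports
            ],
            columns=_REPORT_FIELDS + ["provenance"],
        )
        frame.to_csv(path, index=False, float_format="%.17g")
    else:
        raise SchemaError(f"unsupported report format: {fmt!r}")


def read_reports(path: Union[str, Path], format: Optional[str] = None) -> List[HazardReport]:
    """Read back reports written by :func:`write_report`."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "json":
        data = json.loads(path.read_text())
        return [HazardReport.model_validate(d) for d in data]
    if fmt == "csv":
        frame = pd.read_csv(path)
        if frame.empty:
            return []
        out = []
        for row in frame.to_dict(orient="records"):
            prov = json.loads(row.pop("provenance")) if "provenance" in row else {}
            out.append(HazardReport(provenance=prov, **{f: row[f] for f in _REPORT_FIELDS}))
        return out
    raise SchemaError(f"unsupported report format: {fmt!r}")


#: ARDS-plausible sampling ranges for the synthetic cohort (uniform draws).
DEFAULT_RANGES: Dict[str, tuple] = {
    "c_obs": (15.0, 45.0),        # mL/cmH2O
    "c_pred": (60.0, 100.0),      # mL/cmH2O
    "driving_pressure": (8.0, 18.0),  # cmH2O
    "peep": (5.0, 16.0),          # cmH2O
    "frequency": (14.0, 28.0),    # breaths/min
    "hb": (9.0, 14.0),            # g/dL
    "fio2": (0.4, 0.8),
    "paco2": (35.0, 50.0),        # mmHg
    "svo2": (0.60, 0.75),
    "pvo2": (35.0, 45.0),         # mmHg
    "shunt": (0.05, 0.30),
    "low_vq": (0.02, 0.25),
    "c1_c2_ratio": (2.0, 10.0),
}


def _saturation_for_content(content: float, hb: float) -> tuple:
    """(saturation, po2) reproducing a target O2 content at physiologic tension."""
    po2 = 90.0
    sat = (content - O2_SOLUBILITY * po2) / (HB_O2_CAPACITY * hb)
    if sat > 1.0:
        sat = 1.0
        po2 = (content - HB_O2_CAPACITY * hb) / O2_SOLUBILITY
    return sat, po2


def generate_synthetic_cohort(
    n: int, seed: int = 0, ranges: Optional[Dict[str, tuple]] = None
) -> List[PatientRecord]:
    """Generate ``n`` coherent synthetic ARDS patients, deterministic per seed.

    Mechanics are drawn uniformly from ARDS-plausible ranges; tidal volume
    is set consistently as ``c_obs * driving_pressure``.  Shunt and low-V/Q
    fractions are drawn within the headroom left by the baby-lung fraction
    (so the lung partition stays below 1), and both blood-gas panels are
    constructed from those fractions, guaranteeing content ordering and
    admixture >= shunt for every record.
    """
    if n < 1:
        raise SchemaError(f"cohort size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    rg = dict(DEFAULT_RANGES)
    if ranges:
        rg.update(ranges)

    def draw(name: str) -> float:
        lo, hi = rg[name]
        return float(rng.uniform(lo, hi))

    records = []
    for i in range(n):
        c_obs, c_pred = draw("c_obs"), draw("c_pred")
        dp, peep, freq = draw("driving_pressure"), draw("peep"), draw("frequency")
        vt_l = c_obs * dp / 1000.0
        mech = PatientMechanics(
            c_obs=c_obs,
            c_pred=c_pred,
            cycle=VentilationCycle(
                peep=peep, driving_pressure=dp, tidal_volume=vt_l, frequency=freq
            ),
        )

        # shunt + low V/Q must fit beside the baby lung in the partition
        headroom = 1.0 - c_obs / c_pred
        s_lo, s_hi = rg["shunt"]
        shunt = float(rng.uniform(s_lo, min(s_hi, 0.6 * headroom)))
        v_lo, v_hi = rg["low_vq"]
        low_vq = float(rng.uniform(v_lo, min(v_hi, headroom - shunt)))
        admixture = shunt + low_vq

        hb, fio2, paco2 = draw("hb"), draw("fio2"), draw("paco2")
        svo2, pvo2 = draw("svo2"), draw("pvo2")
        cv = HB_O2_CAPACITY * hb * svo2 + O2_SOLUBILITY * pvo2

        # ambient panel: arterial content fixed by the drawn admixture
        pc = alveolar_po2(fio2, paco2=paco2)
        cc = HB_O2_CAPACITY * hb + O2_SOLUBILITY * pc
        ca = cc - admixture * (cc - cv)
        sao2, pao2 = _saturation_for_content(ca, hb)
        ambient = BloodGasPanel(
            hb=hb, sao2=sao2, svo2=svo2, pao2=pao2, pvo2=pvo2, fio2=fio2, paco2=paco2
        )

        # pure-oxygen panel: only the true shunt depresses arterial content
        pc1 = alveolar_po2(1.0, paco2=paco2)
        cc1 = HB_O2_CAPACITY * hb + O2_SOLUBILITY * pc1
        ca1 = cc1 - shunt * (cc1 - cv)
        sao2_1, pao2_1 = _saturation_for_content(ca1, hb)
        pure = BloodGasPanel(
            hb=hb, sao2=sao2_1, svo2=svo2, pao2=pao2_1, pvo2=pvo2, fio2=1.0, paco2=paco2
        )

        ratio = draw("c1_c2_ratio")
        pair = InterfacePair(c1=2.0, c2=2.0 / ratio)
        records.append(
            PatientRecord(
                identifier=f"synth-{seed:04d}-{i:03d}",
                mechanics=mech,
                ambient_panel=ambient,
                pure_o2_panel=pure,
                interface_pair=pair,
            )
        )
    return records


def cohort_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Flatten records to the :data:`CSV_COLUMNS` table (e.g. for CSV export)."""
    rows = []
    for r in records:
        m, a, p = r.mechanics, r.ambient_panel, r.pure_o2_panel
        rows.append(
            {
                "identifier": r.identifier,
                "c_obs": m.c_obs,
                "c_pred": m.c_pred,
                "peep": m.cycle.peep,
                "driving_pressure": m.cycle.driving_pressure,
                "tidal_volume": m.cycle.tidal_volume,
                "frequency": m.cycle.frequency,
                "c1": r.interface_pair.c1 if r.interface_pair else None,
                "c2": r.interface_pair.c2 if r.interface_pair else None,
                "hb": a.hb,
                "paco2": a.paco2,
                "fio2": a.fio2,
                "sao2": a.sao2,
                "pao2": a.pao2,
                "svo2": a.svo2,
                "pvo2": a.pvo2,
                "sao2_o2": p.sao2,
                "pao2_o2": p.pao2,
                "svo2_o2": p.svo2,
                "pvo2_o2": p.pvo2,
            }
        )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)
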