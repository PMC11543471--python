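"""Data model and file I/O for the supercritical-extraction lipid pipeline.

The pipeline consumes four kinds of inputs:

* a **recovery table** — relative abundance of each annotated lipid under each
  extraction condition (CSV, lipids as rows, conditions as columns);
* an **extraction design** — the factorial set of supercritical CO2–ethanol
  conditions (temperature, pressure, ethanol cosolvent flow);
* **candidate structure sets** — for each ambiguous lipid shorthand, the list
  of isomeric SMILES it may correspond to;
* **sigma profiles** — discretised COSMO surface-charge-density histograms,
  one per molecule, consumed by the activity-coefficient model.

All validation happens at load time; compute stages may assume valid inputs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "LIPID_CLASSES",
    "SIGMA_GRID_BINS",
    "SIGMA_GRID_LIMIT",
    "ExtractionCondition",
    "LipidRecord",
    "RecoveryTable",
    "SigmaProfile",
    "ValidationError",
    "default_sigma_grid",
    "read_candidate_sets",
    "read_design",
    "read_recovery_table",
    "read_sigma_profile",
    "write_candidate_sets",
    "write_design",
    "write_recovery_table",
    "write_sigma_profile",
    "get_logger",
]

logger = logging.getLogger("sfelip")


def get_logger(stage: str) -> logging.LoggerAdapter:
    """Stage-scoped logger; stage name is prepended to every record."""
    return logging.LoggerAdapter(logger, {"stage": stage})


#: Closed vocabulary of lipid classes used throughout the pipeline.  The study
#: system (an extremophile red microalga) is dominated by glycerophospholipids
#: and glycerolipids, with sphingolipids, prenols and fatty acyls as minor
#: classes; "other" catches anything outside those five.
LIPID_CLASSES = (
    "fatty acyls",
    "glycerolipids",
    "glycerophospholipids",
    "sphingolipids",
    "prenols",
    "other",
)

#: Default sigma-profile discretisation: 51 uniform bins on [-0.025, 0.025] e/A^2.
SIGMA_GRID_BINS = 51
SIGMA_GRID_LIMIT = 0.025


def default_sigma_grid() -> np.ndarray:
    """The 51-point sigma grid shared by all profiles, in e/A^2."""
    return np.linspace(-SIGMA_GRID_LIMIT, SIGMA_GRID_LIMIT, SIGMA_GRID_BINS)


class ValidationError(ValueError):
    """Raised for any malformed input file or inconsistent domain object."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExtractionCondition:
    """One supercritical-extraction operating point.

    Parameters
    ----------
    id : str
        Opaque condition label (the bundled design uses "SC1".."SC12").
    temperature : float
        Extraction temperature, degrees C.
    pressure : float
        Extraction pressure, bar.
    ethanol_flow : float
        Ethanol cosolvent flow, mL/min.
    co2_flow : float
        CO2 flow, mL/min (constant 5.0 in the bundled design).
    """

    id: str
    temperature: float
    pressure: float
    ethanol_flow: float
    co2_flow: float = 5.0

    def __post_init__(self) -> None:
        for name in ("temperature", "pressure", "ethanol_flow", "co2_flow"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(
                    f"condition {self.id!r}: {name} must be strictly positive, got {v}"
                )


@dataclass(frozen=True)
class LipidRecord:
    """One annotated lipid: stable key, shorthand annotation, class, and the
    representative structure (filled in by representative selection)."""

    lipid_id: str
    shorthand: str
    lipid_class: str
    smiles: str | None = None

    def __post_init__(self) -> None:
        if self.lipid_class not in LIPID_CLASSES:
            raise ValidationError(
                f"lipid {self.lipid_id!r}: unknown class {self.lipid_class!r} "
                f"(expected one of {', '.join(LIPID_CLASSES)})"
            )


@dataclass
class RecoveryTable:
    """Lipid x condition matrix of relative abundances.

    ``abundance[i, j]`` is the dimensionless relative abundance of lipid ``i``
    under condition ``j``.  Exact zeros mark below-detection (censored) cells
    and are preserved as 0.0 through every read/write cycle.
    """

    lipids: list[LipidRecord]
    conditions: list[ExtractionCondition]
    abundance: np.ndarray

    def __post_init__(self) -> None:
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.abundance.shape != (len(self.lipids), len(self.conditions)):
            raise ValidationError(
                f"abundance shape {self.abundance.shape} inconsistent with "
                f"{len(self.lipids)} lipids x {len(self.conditions)} conditions"
            )
        if not np.all(np.isfinite(self.abundance)):
            raise ValidationError("abundance contains non-finite values")
        if np.any(self.abundance < 0):
            raise ValidationError("negative abundance")
        ids = [l.lipid_id for l in self.lipids]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate lipid_id in recovery table")
        cids = [c.id for c in self.conditions]
        if len(set(cids)) != len(cids):
            raise ValidationError("duplicate condition id in recovery table")

    @property
    def lipid_ids(self) -> list[str]:
        return [l.lipid_id for l in self.lipids]

    @property
    def condition_ids(self) -> list[str]:
        return [c.id for c in self.conditions]

    def to_frame(self) -> pd.DataFrame:
        """Abundance matrix as a DataFrame (lipid_id index, condition columns)."""
        return pd.DataFrame(
            self.abundance, index=self.lipid_ids, columns=self.condition_ids
        )


@dataclass
class SigmaProfile:
    """Discretised COSMO sigma profile of one molecule.

    ``p[k]`` is the surface area (A^2) carrying screening charge density
    ``grid[k]`` (e/A^2); ``sum(p) == area``.  ``area`` and ``volume`` are the
    COSMO cavity surface and volume used by the combinatorial term.
    """

    name: str
    area: float
    volume: float
    grid: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.area <= 0 or self.volume <= 0:
            raise ValidationError(f"profile {self.name!r}: area and volume must be positive")
        if self.grid.ndim != 1 or self.grid.shape != self.p.shape:
            raise ValidationError(f"profile {self.name!r}: grid/p shape mismatch")
        d = np.diff(self.grid)
        if np.any(d <= 0) or not np.allclose(d, d[0], rtol=0, atol=1e-9):
            raise ValidationError(f"profile {self.name!r}: grid not strictly increasing and uniform")
        if np.any(self.p < -1e-12):
            raise ValidationError(f"profile {self.name!r}: negative p")
        self.p = np.clip(self.p, 0.0, None)
        total = float(self.p.sum())
        if abs(total - self.area) > 1e-6 * max(abs(self.area), 1.0):
            raise ValidationError(
                f"profile {self.name!r}: sum(p)={total:.8g} does not match area={self.area:.8g}"
            )

    def normalized(self) -> np.ndarray:
        """p(sigma)/A — the probability a surface segment has density sigma."""
        return self.p / self.area

    def renamed(self, name: str) -> "SigmaProfile":
        return replace(self, name=name)


# ---------------------------------------------------------------------------
# Recovery table I/O
# ---------------------------------------------------------------------------

_META_COLS = ("lipid_id", "shorthand", "lipid_class")


def read_recovery_table(
    path, design: list[ExtractionCondition] | None = None
) -> RecoveryTable:
    """Read a recovery CSV: lipid_id, shorthand, lipid_class, then one
    abundance column per condition id.

    When ``design`` is given, its conditions are matched to the CSV columns by
    id (every column must appear in the design); otherwise placeholder
    conditions with the column labels are created so the table can be handled
    standalone.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip().split(",")
    raw_conds = [c for c in header if c not in _META_COLS]
    if len(set(raw_conds)) != len(raw_conds):
        raise ValidationError("duplicate condition id in recovery CSV header")
    try:
        df = pd.read_csv(path, dtype={c: str for c in _META_COLS})
    except Exception as exc:
        raise ValidationError(f"cannot parse recovery CSV {path}: {exc}") from exc
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"recovery CSV missing columns: {', '.join(missing)}")
    cond_ids = [c for c in df.columns if c not in _META_COLS]
    if not cond_ids:
        raise ValidationError("recovery CSV has no condition columns")
    if df[list(_META_COLS)].isna().any().any():
        raise ValidationError("recovery CSV has ragged rows (missing lipid metadata)")

    values = df[cond_ids].to_numpy()
    num = np.empty(values.shape, dtype=float)
    for (i, j), v in np.ndenumerate(values):
        try:
            num[i, j] = float(v)
        except (TypeError, ValueError):
            raise ValidationError(
                f"non-numeric abundance {v!r} for lipid "
                f"{df['lipid_id'].iloc[i]!r}, condition {cond_ids[j]!r}"
            ) from None
    if np.any(~np.isfinite(num)):
        raise ValidationError("recovery CSV has ragged rows (missing abundance cells)")
    if np.any(num < 0):
        i, j = np.argwhere(num < 0)[0]
        raise ValidationError(
            f"negative abundance {num[i, j]} for lipid "
            f"{df['lipid_id'].iloc[i]!r}, condition {cond_ids[j]!r}"
        )

    if design is not None:
        by_id = {c.id: c for c in design}
        unknown = [c for c in cond_ids if c not in by_id]
        if unknown:
            raise ValidationError(f"conditions not in design: {', '.join(unknown)}")
        conditions = [by_id[c] for c in cond_ids]
    else:
        conditions = [
            ExtractionCondition(id=c, temperature=1.0, pressure=1.0, ethanol_flow=1.0)
            for c in cond_ids
        ]

    lipids = [
        LipidRecord(lipid_id=r.lipid_id, shorthand=r.shorthand, lipid_class=r.lipid_class)
        for r in df[list(_META_COLS)].itertuples(index=False)
    ]
    return RecoveryTable(lipids=lipids, conditions=conditions, abundance=num)


def write_recovery_table(table: RecoveryTable, path) -> None:
    meta = pd.DataFrame(
        {
            "lipid_id": table.lipid_ids,
            "shorthand": [l.shorthand for l in table.lipids],
            "lipid_class": [l.lipid_class for l in table.lipids],
        }
    )
    out = pd.concat([meta, table.to_frame().reset_index(drop=True)], axis=1)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Extraction design I/O
# ---------------------------------------------------------------------------


def read_design(path) -> list[ExtractionCondition]:
    """Read an extraction design CSV with columns
    id, temperature, pressure, ethanol_flow[, co2_flow]."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError("no conditions in design file") from None
    required = ("id", "temperature", "pressure", "ethanol_flow")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"design CSV missing columns: {', '.join(missing)}")
    if len(df) == 0:
        raise ValidationError("no conditions in design file")
    if df["id"].duplicated().any():
        dup = df["id"][df["id"].duplicated()].iloc[0]
        raise ValidationError(f"duplicate condition id {dup!r} in design")
    conditions = []
    for row in df.itertuples(index=False):
        kwargs = dict(
            id=str(row.id),
            temperature=float(row.temperature),
            pressure=float(row.pressure),
            ethanol_flow=float(row.ethanol_flow),
        )
        if "co2_flow" in df.columns and np.isfinite(float(getattr(row, "co2_flow"))):
            kwargs["co2_flow"] = float(getattr(row, "co2_flow"))
        conditions.append(ExtractionCondition(**kwargs))
    return conditions


def write_design(conditions: list[ExtractionCondition], path) -> None:
    pd.DataFrame(
        {
            "id": [c.id for c in conditions],
            "temperature": [c.temperature for c in conditions],
            "pressure": [c.pressure for c in conditions],
            "ethanol_flow": [c.ethanol_flow for c in conditions],
            "co2_flow": [c.co2_flow for c in conditions],
        }
    ).to_csv(path, index=False)


def default_design() -> list[ExtractionCondition]:
    """The bundled 2x3x2 factorial design (12 conditions, SC1..SC12)."""
    from importlib.resources import files

    return read_design(files("sfelip.data").joinpath("design.csv"))


# ---------------------------------------------------------------------------
# Candidate structure sets
# ---------------------------------------------------------------------------


def read_candidate_sets(path) -> dict[str, list[str]]:
    """Read a two-column (shorthand, SMILES) file; candidates grouped by
    shorthand in file order.  File order is the tie-break key downstream, so
    it is preserved exactly.  Delimiter: tab or comma.
    """
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.error")
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split(",")
            if len(parts) < 2:
                raise ValidationError(f"line {lineno}: expected (shorthand, SMILES)")
            shorthand, smi = parts[0].strip(), parts[1].strip()
            if Chem.MolFromSmiles(smi) is None:
                raise ValidationError(f"line {lineno}: invalid SMILES {smi!r}")
            sets.setdefault(shorthand, []).append(smi)
    return sets


def write_candidate_sets(sets: dict[str, list[str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for shorthand, smiles_list in sets.items():
            for smi in smiles_list:
                fh.write(f"{shorthand}\t{smi}\n")


# ---------------------------------------------------------------------------
# Sigma profile I/O (plain-text dialect)
# ---------------------------------------------------------------------------


def read_sigma_profile(path) -> SigmaProfile:
    """Read the text sigma-profile dialect:

    ::

        # name <label>
        # area <A^2>
        # volume <A^3>
        <sigma_1> <p_1>
        ...
    """
    name = None
    area = None
    volume = None
    sigmas: list[float] = []
    ps: list[float] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split(None, 1)
                if len(parts) != 2:
                    raise ValidationError(f"line {lineno}: malformed header {line!r}")
                key, value = parts[0].lower(), parts[1].strip()
                if key == "name":
                    name = value
                elif key == "area":
                    area = float(value)
                elif key == "volume":
                    volume = float(value)
                else:
                    raise ValidationError(f"line {lineno}: unknown header key {key!r}")
            else:
                parts = line.split()
                if len(parts) != 2:
                    raise ValidationError(f"line {lineno}: expected 'sigma p' pair")
                sigmas.append(float(parts[0]))
                ps.append(float(parts[1]))
    if name is None or area is None or volume is None:
        raise ValidationError("sigma-profile header must carry name, area and volume")
    if not sigmas:
        raise ValidationError("sigma profile has no (sigma, p) body")
    return SigmaProfile(name=name, area=area, volume=volume, grid=np.array(sigmas), p=np.array(ps))


def write_sigma_profile(profile: SigmaProfile, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# name {profile.name}\n")
        fh.write(f"# area {float(profile.area)!r}\n")
        fh.write(f"# volume {float(profile.volume)!r}\n")
        for s, p in zip(profile.grid, profile.p):
            fh.write(f"{float(s)!r} {float(p)!r}\n")


def file_sha256(path) -> str:
    """Fingerprint of an input file, recorded in run manifests."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
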