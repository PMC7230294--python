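"""Metabolite panel and paired-sample data model.

The targeted assay quantifies a fixed catalogue of metabolites, each with a
lower and upper limit of quantitation (LLOQ / ULOQ, in µM).  The study design
is strictly paired: every patient contributes one sample drawn during a
vaso-occlusive crisis ("IC", in-crisis) and one at steady state ("OC",
out-of-crisis), from a single sample matrix (plasma or washed erythrocytes).

This module defines

* :class:`PanelSpec` — the metabolite catalogue with biochemical class labels
  and quantitation bounds;
* :class:`SampleKey` / :class:`PairedDataset` — the paired concentration table
  with per-cell censoring flags;
* CSV readers/writers for both, plus the bundled 188-metabolite default panel
  shaped like a Biocrates AbsoluteIDQ p180 kit (1 free carnitine, 39
  acyl-carnitines, 1 hexose sum, 21 amino acids, 21 biogenic amines, 14
  lysophosphatidylcholines, 38 diacyl-PC, 38 acyl-alkyl-PC, 15 sphingomyelins).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from enum import IntEnum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("pairedpls")

STATES = ("IC", "OC")
MATRICES = ("plasma", "rbc")

CLASS_LABELS = (
    "free_carnitine",
    "acylcarnitine",
    "hexose",
    "amino_acid",
    "biogenic_amine",
    "lysoPC",
    "PC_aa",
    "PC_ae",
    "sphingomyelin",
)

#: Per-class entry counts of the default 188-metabolite kit panel.
KIT_CLASS_COUNTS = {
    "free_carnitine": 1,
    "acylcarnitine": 39,
    "hexose": 1,
    "amino_acid": 21,
    "biogenic_amine": 21,
    "lysoPC": 14,
    "PC_aa": 38,
    "PC_ae": 38,
    "sphingomyelin": 15,
}

LIPID_CLASSES = ("lysoPC", "PC_aa", "PC_ae", "sphingomyelin")


class PanelError(ValueError):
    """Panel file or panel invariant violation."""


class DatasetError(ValueError):
    """Concentration table or pairing invariant violation."""


class CensorFlag(IntEnum):
    OK = 0
    BELOW_LLOQ = 1
    ABOVE_ULOQ = 2


# ---------------------------------------------------------------------------
# Panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelEntry:
    metabolite_id: str
    class_label: str
    lloq: float  # µM
    uloq: float  # µM
    acyl_carbons: int | None = None  # LPC/SM chain-length annotation


@dataclass
class PanelSpec:
    """Validated metabolite catalogue; entry order is canonical downstream."""

    entries: list[PanelEntry]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.metabolite_id in seen:
                raise PanelError(f"duplicate metabolite id: {e.metabolite_id!r}")
            seen.add(e.metabolite_id)
            if e.class_label not in CLASS_LABELS:
                raise PanelError(
                    f"unknown class label {e.class_label!r} for {e.metabolite_id!r}"
                )
            if not (0 <= e.lloq < e.uloq):
                raise PanelError(
                    f"require 0 <= lloq < uloq for {e.metabolite_id!r} "
                    f"(got lloq={e.lloq}, uloq={e.uloq})"
                )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def ids(self) -> list[str]:
        return [e.metabolite_id for e in self.entries]

    def entry(self, metabolite_id: str) -> PanelEntry:
        try:
            return self._index[metabolite_id]
        except AttributeError:
            object.__setattr__(
                self, "_index", {e.metabolite_id: e for e in self.entries}
            )
            return self._index[metabolite_id]

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.entries:
            counts[e.class_label] = counts.get(e.class_label, 0) + 1
        return counts

    def bounds(self, metabolite_ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """(lloq, uloq) arrays aligned with ``metabolite_ids``."""
        lloq = np.array([self.entry(m).lloq for m in metabolite_ids], float)
        uloq = np.array([self.entry(m).uloq for m in metabolite_ids], float)
        return lloq, uloq

    def subset(self, metabolite_ids: Iterable[str]) -> "PanelSpec":
        wanted = set(metabolite_ids)
        return PanelSpec([e for e in self.entries if e.metabolite_id in wanted])


def load_panel(path: str | Path) -> PanelSpec:
    """Read a panel file (CSV with header ``metabolite_id,class,lloq,uloq
    [,acyl_carbons]``, or an equivalent JSON list of records)."""
    path = Path(path)
    if not path.exists():
        raise PanelError(f"panel file not found: {path}")
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        df = pd.DataFrame.from_records(records)
    else:
        df = pd.read_csv(path, dtype={"metabolite_id": str, "class": str})
    required = {"metabolite_id", "class", "lloq", "uloq"}
    missing = required - set(df.columns)
    if missing:
        raise PanelError(f"panel file missing columns: {sorted(missing)}")
    entries = []
    for rec in df.to_dict("records"):
        acyl = rec.get("acyl_carbons")
        acyl = None if acyl is None or (isinstance(acyl, float) and np.isnan(acyl)) else int(acyl)
        entries.append(
            PanelEntry(
                metabolite_id=str(rec["metabolite_id"]),
                class_label=str(rec["class"]),
                lloq=float(rec["lloq"]),
                uloq=float(rec["uloq"]),
                acyl_carbons=acyl,
            )
        )
    panel = PanelSpec(entries)
    log.info(
        "load_panel path=%s n_entries=%d class_counts=%s",
        path, len(panel), panel.class_counts(),
    )
    return panel


def write_panel(panel: PanelSpec, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "metabolite_id": [e.metabolite_id for e in panel.entries],
            "class": [e.class_label for e in panel.entries],
            "lloq": [e.lloq for e in panel.entries],
            "uloq": [e.uloq for e in panel.entries],
            "acyl_carbons": [e.acyl_carbons for e in panel.entries],
        }
    )
    df["acyl_carbons"] = df["acyl_carbons"].astype("Int64")
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Default kit-shaped panel
# ---------------------------------------------------------------------------

_ACYLCARNITINES = [
    "C2", "C3", "C3:1", "C3-OH", "C3-DC", "C4", "C4:1", "C4-OH",
    "C5", "C5:1", "C5-OH", "C5-DC", "C5-M-DC", "C6", "C6:1", "C7-DC",
    "C8", "C9", "C10", "C10:1", "C10:2", "C12", "C12:1", "C12-DC",
    "C14", "C14:1", "C14:1-OH", "C14:2", "C14:2-OH",
    "C16", "C16:1", "C16:1-OH", "C16:2", "C16:2-OH", "C16-OH",
    "C18", "C18:1", "C18:1-OH", "C18:2",
]

_AMINO_ACIDS = [
    "Ala", "Arg", "Asn", "Asp", "Cit", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Orn", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr",
    "Val",
]

_BIOGENIC_AMINES = [
    "ADMA", "SDMA", "total DMA", "alpha-AAA", "c4-OH-Pro", "t4-OH-Pro",
    "Carnosine", "Creatinine", "DOPA", "Dopamine", "Histamine", "Kynurenine",
    "Met-SO", "Nitro-Tyr", "PEA", "Putrescine", "Sarcosine", "Serotonin",
    "Spermidine", "Spermine", "Taurine",
]

_LYSOPC = [
    "lysoPC a C14:0", "lysoPC a C16:0", "lysoPC a C16:1", "lysoPC a C17:0",
    "lysoPC a C18:0", "lysoPC a C18:1", "lysoPC a C18:2", "lysoPC a C20:3",
    "lysoPC a C20:4", "lysoPC a C24:0", "lysoPC a C26:0", "lysoPC a C26:1",
    "lysoPC a C28:0", "lysoPC a C28:1",
]

_PC_AA = [(24, 0), (26, 0), (28, 1), (30, 0), (30, 2), (32, 0), (32, 1),
          (32, 2), (32, 3), (34, 1), (34, 2), (34, 3), (34, 4), (36, 0),
          (36, 1), (36, 2), (36, 3), (36, 4), (36, 5), (36, 6), (38, 0),
          (38, 1), (38, 3), (38, 4), (38, 5), (38, 6), (40, 1), (40, 2),
          (40, 3), (40, 4), (40, 5), (40, 6), (42, 0), (42, 1), (42, 2),
          (42, 4), (42, 5), (42, 6)]

_PC_AE = [(30, 0), (30, 1), (30, 2), (32, 1), (32, 2), (34, 0), (34, 1),
          (34, 2), (34, 3), (36, 0), (36, 1), (36, 2), (36, 3), (36, 4),
          (36, 5), (38, 0), (38, 1), (38, 2), (38, 3), (38, 4), (38, 5),
          (38, 6), (40, 1), (40, 2), (40, 3), (40, 4), (40, 5), (40, 6),
          (42, 1), (42, 2), (42, 3), (42, 4), (42, 5), (44, 3), (44, 4),
          (44, 5), (44, 6), (46, 3)]

_SM = [
    "SM C16:0", "SM C16:1", "SM C18:0", "SM C18:1", "SM C20:2", "SM C22:3",
    "SM C24:0", "SM C24:1", "SM C26:0", "SM C26:1", "SM (OH) C14:1",
    "SM (OH) C16:1", "SM (OH) C22:1", "SM (OH) C22:2", "SM (OH) C24:1",
]

# class -> (lo, hi) of typical median concentration, µM (log-uniform draw)
_CLASS_MEDIAN_RANGE = {
    "free_carnitine": (25.0, 50.0),
    "acylcarnitine": (0.02, 2.0),
    "hexose": (3000.0, 6000.0),
    "amino_acid": (10.0, 400.0),
    "biogenic_amine": (0.05, 20.0),
    "lysoPC": (0.3, 100.0),
    "PC_aa": (0.5, 200.0),
    "PC_ae": (0.3, 20.0),
    "sphingomyelin": (3.0, 150.0),
}

_CHAIN_RE = re.compile(r"C(\d+):\d+\s*$")


def _chain_carbons(name: str) -> int | None:
    m = _CHAIN_RE.search(name)
    return int(m.group(1)) if m else None


def build_default_panel() -> PanelSpec:
    """Construct the bundled kit-shaped 188-metabolite panel.

    Identities follow the kit's published class structure; quantitation
    bounds are synthetic but class-realistic (the real kit's LLOQ/ULOQ values
    are not public).  A fixed internal seed makes the panel a constant.
    """
    rng = np.random.default_rng(20200411)
    names: list[tuple[str, str, int | None]] = [("C0", "free_carnitine", None)]
    names += [(n, "acylcarnitine", None) for n in _ACYLCARNITINES]
    names += [("H1", "hexose", None)]
    names += [(n, "amino_acid", None) for n in _AMINO_ACIDS]
    names += [(n, "biogenic_amine", None) for n in _BIOGENIC_AMINES]
    names += [(n, "lysoPC", _chain_carbons(n)) for n in _LYSOPC]
    names += [(f"PC aa C{c}:{d}", "PC_aa", None) for c, d in _PC_AA]
    names += [(f"PC ae C{c}:{d}", "PC_ae", None) for c, d in _PC_AE]
    names += [(n, "sphingomyelin", _chain_carbons(n)) for n in _SM]

    entries = []
    for name, cls, acyl in names:
        lo, hi = _CLASS_MEDIAN_RANGE[cls]
        median = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        lloq = float(np.format_float_positional(median / 20.0, precision=6,
                                                unique=False, fractional=False))
        uloq = float(np.format_float_positional(median * 20.0, precision=6,
                                                unique=False, fractional=False))
        entries.append(PanelEntry(name, cls, lloq, uloq, acyl))
    panel = PanelSpec(entries)
    assert panel.class_counts() == KIT_CLASS_COUNTS
    return panel


def default_panel_path() -> Path:
    return Path(str(resources.files("pairedpls").joinpath("data/default_panel.csv")))


def default_panel() -> PanelSpec:
    """The bundled 188-metabolite kit-shaped panel."""
    return load_panel(default_panel_path())


# ---------------------------------------------------------------------------
# Paired dataset
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class SampleKey:
    patient_id: str
    state: str  # "IC" | "OC"
    matrix: str = "plasma"

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise DatasetError(f"unknown state {self.state!r} (expected IC/OC)")
        if self.matrix not in MATRICES:
            raise DatasetError(f"unknown matrix {self.matrix!r} (expected plasma/rbc)")


@dataclass
class PairedDataset:
    """Sample × metabolite concentration grid with censoring flags.

    Rows are samples (one per patient and state, a single matrix per
    dataset), columns are metabolites in panel order.  ``values`` holds µM
    concentrations; ``flags`` marks each cell OK / BELOW_LLOQ / ABOVE_ULOQ.
    """

    samples: list[SampleKey]
    metabolites: list[str]
    values: np.ndarray
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.flags is None:
            self.flags = np.zeros(self.values.shape, dtype=np.int8)
        self.flags = np.asarray(self.flags, dtype=np.int8)
        n_s, n_m = len(self.samples), len(self.metabolites)
        if self.values.shape != (n_s, n_m) or self.flags.shape != (n_s, n_m):
            raise DatasetError(
                f"grid shape mismatch: {self.values.shape} vs "
                f"({n_s} samples, {n_m} metabolites)"
            )
        if len(set(self.samples)) != n_s:
            raise DatasetError("duplicate SampleKey in dataset")
        if len(set(self.metabolites)) != n_m:
            raise DatasetError("duplicate metabolite id in dataset")
        if np.isnan(self.values).any():
            raise DatasetError("missing concentration cells are not allowed")
        matrices = {s.matrix for s in self.samples}
        if len(matrices) > 1:
            raise DatasetError(f"mixed sample matrices in one dataset: {sorted(matrices)}")
        self._check_pairing()

    def _check_pairing(self) -> None:
        states_by_patient: dict[str, set[str]] = {}
        for s in self.samples:
            states_by_patient.setdefault(s.patient_id, set()).add(s.state)
        broken = sorted(p for p, st in states_by_patient.items() if st != {"IC", "OC"})
        if broken:
            raise DatasetError(
                "unpaired patients (need exactly one IC and one OC sample): "
                + ", ".join(broken)
            )

    # -- basic accessors ----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_cells(self) -> int:
        return self.values.size

    @property
    def matrix(self) -> str:
        return self.samples[0].matrix

    @property
    def patients(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.patient_id, None)
        return list(seen)

    @property
    def y(self) -> np.ndarray:
        """Class code per sample: IC=1, OC=0."""
        return np.array([1.0 if s.state == "IC" else 0.0 for s in self.samples])

    @property
    def pair_ids(self) -> np.ndarray:
        """Patient label per row (used to keep pairs intact in splits)."""
        return np.array([s.patient_id for s in self.samples])

    def metabolite_index(self, metabolite_ids: Sequence[str]) -> np.ndarray:
        pos = {m: j for j, m in enumerate(self.metabolites)}
        return np.array([pos[m] for m in metabolite_ids], int)

    def subset_metabolites(self, metabolite_ids: Sequence[str]) -> "PairedDataset":
        idx = self.metabolite_index(metabolite_ids)
        return PairedDataset(
            samples=list(self.samples),
            metabolites=list(metabolite_ids),
            values=self.values[:, idx].copy(),
            flags=self.flags[:, idx].copy(),
        )

    def rows_for_patients(self, patient_ids: Sequence[str]) -> np.ndarray:
        wanted = set(patient_ids)
        return np.array(
            [i for i, s in enumerate(self.samples) if s.patient_id in wanted], int
        )

    def to_frame(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            {
                "patient_id": [s.patient_id for s in self.samples],
                "state": [s.state for s in self.samples],
                "matrix": [s.matrix for s in self.samples],
            }
        )
        vals = pd.DataFrame(self.values, columns=self.metabolites)
        return pd.concat([meta, vals], axis=1)


_META_COLS = ("patient_id", "state", "matrix")


def load_concentrations(path: str | Path, panel: PanelSpec) -> PairedDataset:
    """Read a wide concentration CSV and derive censoring flags from ``panel``.

    Metabolite columns absent from the panel are dropped with a warning;
    columns are re-ordered to panel order; missing cells, duplicate sample
    keys and unpaired patients are validation failures.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        dtype={"patient_id": str, "state": str, "matrix": str},
        float_precision="round_trip",
    )
    missing_meta = [c for c in _META_COLS if c not in df.columns]
    if missing_meta:
        raise DatasetError(f"{path}: missing metadata columns {missing_meta}")
    met_cols = [c for c in df.columns if c not in _META_COLS]
    panel_ids = set(panel.ids)
    unknown = [c for c in met_cols if c not in panel_ids]
    if unknown:
        log.warning(
            "load_concentrations path=%s dropped_columns=%d not_in_panel=%s",
            path, len(unknown), unknown,
        )
    kept = [m for m in panel.ids if m in met_cols]  # canonical panel order
    samples = [
        SampleKey(str(r.patient_id), str(r.state), str(r.matrix))
        for r in df.itertuples(index=False)
    ]
    values = df[kept].to_numpy(float)
    if np.isnan(values).any():
        bad = [kept[j] for j in np.unique(np.where(np.isnan(values))[1])]
        raise DatasetError(f"{path}: empty concentration cells in columns {bad}")
    lloq, uloq = panel.bounds(kept)
    flags = np.zeros(values.shape, dtype=np.int8)
    flags[values < lloq] = CensorFlag.BELOW_LLOQ
    flags[values > uloq] = CensorFlag.ABOVE_ULOQ
    ds = PairedDataset(samples=samples, metabolites=kept, values=values, flags=flags)
    log.info(
        "load_concentrations path=%s n_samples=%d n_metabolites=%d n_cells=%d",
        path, ds.n_samples, ds.n_metabolites, ds.n_cells,
    )
    return ds


def write_dataset(dataset: PairedDataset, path: str | Path) -> None:
    """Write the wide CSV form; values use 17 significant digits so a
    write→load cycle is the identity on float64 values (and, via the same
    panel, on flags)."""
    dataset.to_frame().to_csv(path, index=False, float_format="%.17g")
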