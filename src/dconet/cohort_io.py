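"""Domain containers and readers/writers for cohort-level inputs.

The central object is the :class:`AlterationMatrix`, a binary sample x gene
driver-alteration table (1 = the gene carries a driver alteration in that
sample).  Around it live the treatment metadata (:class:`TreatmentArm`),
gene-level biomarker annotations (:class:`BiomarkerCatalog`), targeted
sequencing panels (:class:`GenePanel`), genomic coordinates used for linkage
annotation (:class:`GeneCoordinates`), and clinical outcome tables
(:class:`OutcomeTable`).

File conventions
----------------
* matrices: wide TSV (rows = samples, columns = genes, values 0/1) is the
  canonical format; long TSV (``sample<TAB>gene``, one row per altered pair)
  is accepted as convenience input.
* panels: one gene symbol per line.
* coordinates: BED4 (``chrom  start  end  gene``; 0-based half-open) plus an
  optional arm-annotation TSV (``gene  arm``).
* all readers tolerate CRLF line endings and ``#`` comment lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AlterationMatrix",
    "TreatmentArm",
    "BiomarkerCatalog",
    "BiomarkerRecord",
    "GenePanel",
    "GeneCoordinates",
    "OutcomeTable",
    "FormatError",
    "EmptyPanelError",
    "read_alteration_matrix",
    "write_alteration_matrix",
    "read_panel",
    "read_biomarker_catalog",
    "read_coordinates",
    "read_outcomes",
    "write_outcomes",
    "read_predictions",
    "write_predictions",
    "write_network",
    "read_network",
    "subset_to_panel",
]


class FormatError(ValueError):
    """Raised when an input file violates the documented format."""


class EmptyPanelError(ValueError):
    """Raised when a panel intersection leaves no genes."""


def _read_lines(path):
    with open(path, "r", newline="") as fh:
        for raw in fh:
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            yield line


@dataclass
class AlterationMatrix:
    """Binary sample x gene driver-alteration matrix.

    ``status[i, j] == 1`` iff sample ``sample_ids[i]`` carries a driver
    alteration in gene ``gene_ids[j]``.
    """

    sample_ids: list[str]
    gene_ids: list[str]
    status: np.ndarray  # shape (n_samples, n_genes), dtype uint8

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status)
        if self.status.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError("status shape does not match identifier lists")
        if not np.isin(self.status, (0, 1)).all():
            raise FormatError("alteration matrix entries must be 0 or 1")
        self.status = self.status.astype(np.uint8)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def sample_index(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([lookup[s] for s in sample_ids], dtype=int)

    def gene_index(self, gene_ids) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in gene_ids], dtype=int)

    def row_sums(self) -> np.ndarray:
        """Per-sample driver counts."""
        return self.status.sum(axis=1).astype(int)

    def col_sums(self) -> np.ndarray:
        """Per-gene alteration counts."""
        return self.status.sum(axis=0).astype(int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.status, index=self.sample_ids, columns=self.gene_ids)

    def subset_samples(self, sample_ids) -> "AlterationMatrix":
        idx = self.sample_index(sample_ids)
        return AlterationMatrix(list(sample_ids), list(self.gene_ids), self.status[idx])

    def copy(self) -> "AlterationMatrix":
        return AlterationMatrix(list(self.sample_ids), list(self.gene_ids), self.status.copy())


@dataclass
class TreatmentArm:
    """Samples treated with one regimen and their binary response labels.

    ``binary_response`` maps sample id -> True (responder) / False
    (non-responder).  Arms with fewer than ``min_group`` samples in either
    response group carry too little inter-individual heterogeneity to model.
    """

    treatment_id: str
    binary_response: dict[str, bool]
    drug_families: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.binary_response)

    @property
    def responders(self) -> list[str]:
        return [s for s, r in self.binary_response.items() if r]

    @property
    def non_responders(self) -> list[str]:
        return [s for s, r in self.binary_response.items() if not r]

    def is_eligible(self, min_group: int = 5) -> bool:
        return len(self.responders) >= min_group and len(self.non_responders) >= min_group

    def validate_against(self, matrix: AlterationMatrix) -> None:
        missing = set(self.binary_response) - set(matrix.sample_ids)
        if missing:
            raise ValueError(
                f"arm {self.treatment_id}: {len(missing)} samples missing from matrix"
            )


@dataclass(frozen=True)
class BiomarkerRecord:
    gene: str
    drug_family: str
    direction: str  # "response" | "non-response"
    evidence_tier: str = "experimental"  # "approved" | "experimental"

    def __post_init__(self) -> None:
        if self.direction not in ("response", "non-response"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.evidence_tier not in ("approved", "experimental"):
            raise ValueError(f"bad evidence tier {self.evidence_tier!r}")


@dataclass
class BiomarkerCatalog:
    """Gene-level response / non-response biomarker annotations per drug family."""

    records: list[BiomarkerRecord]

    def __post_init__(self) -> None:
        keys = [(r.gene, r.drug_family, r.direction) for r in self.records]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (gene, drug_family, direction) records")

    def for_family(self, drug_family: str) -> list[BiomarkerRecord]:
        return [r for r in self.records if r.drug_family == drug_family]

    def genes(self, drug_family: str | None = None) -> list[str]:
        recs = self.records if drug_family is None else self.for_family(drug_family)
        return sorted({r.gene for r in recs})


@dataclass
class GenePanel:
    """A targeted-sequencing gene panel (e.g. a 410- or 287-gene capture design)."""

    panel_id: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValueError("empty gene panel")


@dataclass
class GeneCoordinates:
    """Genomic coordinates per gene, 0-based half-open (BED dialect).

    ``arms`` maps gene -> chromosome arm ("p"/"q"/"unknown"); used to flag
    driver pairs that are genomically linked and hence co-altered for
    structural rather than selective reasons.
    """

    coords: dict[str, tuple[str, int, int]]  # gene -> (chrom, start, end)
    arms: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, (chrom, start, end) in self.coords.items():
            if not start < end:
                raise ValueError(f"{gene}: start must be < end (0-based half-open)")
        for gene, arm in self.arms.items():
            if arm not in ("p", "q", "unknown"):
                raise ValueError(f"{gene}: arm must be p/q/unknown")

    def arm_of(self, gene: str) -> str:
        return self.arms.get(gene, "unknown")

    def same_arm(self, gene_a: str, gene_b: str) -> bool:
        """True when both genes map to the same chromosome arm."""
        ca = self.coords.get(gene_a)
        cb = self.coords.get(gene_b)
        if ca is None or cb is None or ca[0] != cb[0]:
            return False
        arm_a, arm_b = self.arm_of(gene_a), self.arm_of(gene_b)
        if arm_a == "unknown" or arm_b == "unknown":
            return False
        return arm_a == arm_b

    def distance_bp(self, gene_a: str, gene_b: str) -> int | None:
        """Gap between the two gene bodies in bp; 0 if overlapping; None if
        on different chromosomes or missing."""
        ca = self.coords.get(gene_a)
        cb = self.coords.get(gene_b)
        if ca is None or cb is None or ca[0] != cb[0]:
            return None
        gap = max(ca[1], cb[1]) - min(ca[2], cb[2])
        return max(gap, 0)


@dataclass
class OutcomeTable:
    """Per-patient continuous clinical outcome (treatment duration / PFS).

    ``event`` is 1 when progression was observed, 0 when the duration is
    right-censored.
    """

    patient_ids: list[str]
    durations: np.ndarray  # months, > 0
    events: np.ndarray  # 1 = progressed, 0 = censored
    biopsy_offset_days: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if not (self.durations > 0).all():
            raise ValueError("durations must be > 0")
        if not np.isin(self.events, (0, 1)).all():
            raise ValueError("event flags must be 0/1")
        if len(self.patient_ids) != len(self.durations) or len(self.durations) != len(self.events):
            raise ValueError("column lengths differ")

    def __len__(self) -> int:
        return len(self.patient_ids)

    def filter_biopsy_offset(self, max_days: float = 60.0) -> "OutcomeTable":
        """Drop patients whose biopsy postdates therapy start by > max_days."""
        if self.biopsy_offset_days is None:
            return self
        keep = np.asarray(self.biopsy_offset_days, dtype=float) <= max_days
        return OutcomeTable(
            [p for p, k in zip(self.patient_ids, keep) if k],
            self.durations[keep],
            self.events[keep],
            np.asarray(self.biopsy_offset_days, dtype=float)[keep],
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_alteration_matrix(path, format: str = "wide_tsv") -> AlterationMatrix:
    """Read a binary alteration matrix.

    ``wide_tsv``: header row of gene ids, first column sample ids, 0/1 cells.
    ``long_tsv``: two columns ``sample<TAB>gene``, one row per altered pair;
    duplicates collapse to a single 1.
    """
    lines = list(_read_lines(path))
    if not lines:
        raise FormatError(f"{path}: empty file")
    if format == "wide_tsv":
        header = lines[0].split("\t")
        genes = header[1:]
        samples, rows = [], []
        for line in lines[1:]:
            parts = line.split("\t")
            if len(parts) != len(genes) + 1:
                raise FormatError(f"{path}: ragged row for sample {parts[0]!r}")
            samples.append(parts[0])
            try:
                row = [int(v) for v in parts[1:]]
            except ValueError as exc:
                raise FormatError(f"{path}: non-integer cell in row {parts[0]!r}") from exc
            if any(v not in (0, 1) for v in row):
                raise FormatError(f"{path}: non-binary value in row {parts[0]!r}")
            rows.append(row)
        if not samples:
            raise FormatError(f"{path}: no sample rows")
        return AlterationMatrix(samples, genes, np.array(rows, dtype=np.uint8))
    if format == "long_tsv":
        pairs = []
        for line in lines:
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}: long format needs sample<TAB>gene")
            pairs.append((parts[0], parts[1]))
        if pairs and pairs[0] == ("sample", "gene"):  # optional header
            pairs = pairs[1:]
        if not pairs:
            raise FormatError(f"{path}: no (sample, gene) rows")
        samples = sorted({s for s, _ in pairs})
        genes = sorted({g for _, g in pairs})
        si = {s: i for i, s in enumerate(samples)}
        gi = {g: i for i, g in enumerate(genes)}
        status = np.zeros((len(samples), len(genes)), dtype=np.uint8)
        for s, g in pairs:
            status[si[s], gi[g]] = 1
        return AlterationMatrix(samples, genes, status)
    raise ValueError(f"unknown matrix format {format!r}")


def write_alteration_matrix(matrix: AlterationMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(matrix.gene_ids) + "\n")
        for i, sample in enumerate(matrix.sample_ids):
            fh.write(sample + "\t" + "\t".join(map(str, matrix.status[i])) + "\n")


def read_panel(path, panel_id: str | None = None) -> GenePanel:
    genes = set(_read_lines(path))
    return GenePanel(panel_id or str(path), frozenset(genes))


def read_biomarker_catalog(path) -> BiomarkerCatalog:
    """TSV with header: gene, drug_family, direction, evidence_tier."""
    lines = list(_read_lines(path))
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    required = ["gene", "drug_family", "direction"]
    if header[: len(required)] != required:
        raise FormatError(f"{path}: expected header gene, drug_family, direction[, evidence_tier]")
    records = []
    for line in lines[1:]:
        parts = line.split("\t")
        tier = parts[3] if len(parts) > 3 else "experimental"
        records.append(BiomarkerRecord(parts[0], parts[1], parts[2], tier))
    return BiomarkerCatalog(records)


def read_coordinates(bed_path, arms_path=None) -> GeneCoordinates:
    """Read gene coordinates from BED4 plus an optional gene->arm TSV."""
    coords = {}
    for line in _read_lines(bed_path):
        parts = line.split("\t")
        if len(parts) < 4:
            raise FormatError(f"{bed_path}: BED4 requires chrom, start, end, gene")
        chrom, start, end, gene = parts[0], int(parts[1]), int(parts[2]), parts[3]
        coords[gene] = (chrom, start, end)
    arms = {}
    if arms_path is not None:
        for line in _read_lines(arms_path):
            gene, arm = line.split("\t")[:2]
            arms[gene] = arm
    return GeneCoordinates(coords, arms)


def read_outcomes(path) -> OutcomeTable:
    """CSV with header patient_id, duration_months, event[, biopsy_offset_days]."""
    df = pd.read_csv(path, comment="#")
    required = {"patient_id", "duration_months", "event"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    offsets = (
        df["biopsy_offset_days"].to_numpy(float) if "biopsy_offset_days" in df.columns else None
    )
    return OutcomeTable(
        df["patient_id"].astype(str).tolist(),
        df["duration_months"].to_numpy(float),
        df["event"].to_numpy(int),
        offsets,
    )


def write_outcomes(table: OutcomeTable, path) -> None:
    data = {
        "patient_id": table.patient_ids,
        "duration_months": table.durations,
        "event": table.events,
    }
    if table.biopsy_offset_days is not None:
        data["biopsy_offset_days"] = table.biopsy_offset_days
    pd.DataFrame(data).to_csv(path, index=False)


def write_predictions(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_predictions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_network(network, path, format: str = "graphml") -> None:
    """Export a DCO network (GraphML or SIF); see :mod:`dconet.network`."""
    from .network import write_network as _write

    _write(network, path, format)


def read_network(path, format: str = "graphml"):
    """Read a DCO network back from GraphML; see :mod:`dconet.network`."""
    from .network import read_network as _read

    return _read(path, format)


def subset_to_panel(matrix: AlterationMatrix, panel: GenePanel) -> AlterationMatrix:
    """Restrict the matrix to genes covered by a targeted panel.

    Genes in the panel but absent from the matrix are ignored (with a logged
    count); an empty intersection is an error.
    """
    keep = [g for g in matrix.gene_ids if g in panel.genes]
    if not keep:
        raise EmptyPanelError(
            f"panel {panel.panel_id!r} shares no genes with the alteration matrix"
        )
    ignored = len(panel.genes) - len(set(keep))
    if ignored:
        logger.info("panel %s: %d genes absent from matrix, ignored", panel.panel_id, ignored)
    idx = matrix.gene_index(keep)
    return AlterationMatrix(list(matrix.sample_ids), keep, matrix.status[:, idx])
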