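"""Shared data containers and their on-disk formats.

Multi-locus alignments (one FASTA per locus, headers = sample IDs), sample
metadata tables (CSV), labelled distance matrices (CSV with a header row of
labels), binary host-parasite association tables (CSV, rows = parasites,
columns = hosts) and plain-text cost rasters.

Gaps '-' and 'N' both mean "missing" downstream: market samples are degraded
and partial sequences are the norm, so missingness is a first-class state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, ValidationError

__all__ = [
    "MultiLocusAlignment",
    "SampleTable",
    "DistanceMatrix",
    "AssociationMatrix",
    "CostRaster",
    "read_multilocus_fasta",
    "write_multilocus_fasta",
    "read_sample_table",
    "DEFAULT_REGIONS",
]

ALPHABET = set("ACGT-N")
DEFAULT_REGIONS = ("QTP", "Hengduan", "Himalaya", "Transition")


# --------------------------------------------------------------- alignments
class MultiLocusAlignment:
    """Per-locus aligned sequences keyed by sample ID, with a presence mask.

    ``data`` maps locus name -> {sample ID -> aligned sequence}; a sample
    absent from a locus is simply missing from that inner mapping.
    """

    def __init__(self, loci: Sequence[str], data: Mapping[str, Mapping[str, str]]):
        self.loci = list(loci)
        if len(set(self.loci)) != len(self.loci):
            raise ValidationError("locus names must be unique")
        self.data: dict[str, dict[str, str]] = {}
        for locus in self.loci:
            seqs = {sid: s.upper() for sid, s in dict(data[locus]).items()}
            lengths = {len(s) for s in seqs.values()}
            if len(lengths) > 1:
                offender = max(seqs, key=lambda sid: len(seqs[sid]))
                raise AlignmentError(
                    f"ragged alignment in locus {locus!r} (sample {offender!r})"
                )
            for sid, s in seqs.items():
                bad = set(s) - ALPHABET
                if bad:
                    raise AlignmentError(
                        f"illegal characters {sorted(bad)} in locus {locus!r}, "
                        f"sample {sid!r}"
                    )
            self.data[locus] = seqs
        self._samples = sorted({sid for seqs in self.data.values() for sid in seqs})
        if not self._samples:
            raise AlignmentError("alignment contains no samples")

    @property
    def samples(self) -> list[str]:
        return list(self._samples)

    def locus_length(self, locus: str) -> int:
        seqs = self.data[locus]
        return len(next(iter(seqs.values()))) if seqs else 0

    def has_locus(self, sample: str, locus: str) -> bool:
        return sample in self.data[locus]

    def presence_mask(self) -> pd.DataFrame:
        """Boolean samples x loci table: True where the sample has the locus."""
        mask = pd.DataFrame(
            False, index=self.samples, columns=self.loci, dtype=bool
        )
        for locus in self.loci:
            for sid in self.data[locus]:
                mask.loc[sid, locus] = True
        return mask

    def loci_of(self, sample: str) -> list[str]:
        return [l for l in self.loci if sample in self.data[l]]

    def concatenate(
        self, loci: Sequence[str] | None = None, samples: Sequence[str] | None = None
    ) -> dict[str, str]:
        """Concatenate selected loci; absent loci are padded with 'N'."""
        loci = list(loci) if loci is not None else list(self.loci)
        unknown = set(loci) - set(self.loci)
        if unknown:
            raise ValidationError(f"unknown loci: {sorted(unknown)}")
        samples = list(samples) if samples is not None else self.samples
        out = {}
        for sid in samples:
            parts = []
            for locus in loci:
                seqs = self.data[locus]
                if sid in seqs:
                    parts.append(seqs[sid])
                else:
                    parts.append("N" * self.locus_length(locus))
            out[sid] = "".join(parts)
        return out

    def subset_samples(self, samples: Iterable[str]) -> "MultiLocusAlignment":
        keep = set(samples)
        return MultiLocusAlignment(
            self.loci,
            {
                locus: {sid: s for sid, s in seqs.items() if sid in keep}
                for locus, seqs in self.data.items()
            },
        )


def read_multilocus_fasta(paths: Mapping[str, str | Path]) -> MultiLocusAlignment:
    """Read one FASTA per locus; mapping is locus name -> path."""
    data: dict[str, dict[str, str]] = {}
    for locus, path in paths.items():
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise AlignmentError(f"empty FASTA for locus {locus!r}: {path}")
        seqs: dict[str, str] = {}
        for rec in records:
            if rec.id in seqs:
                raise AlignmentError(
                    f"duplicate sample {rec.id!r} in locus {locus!r}"
                )
            seqs[rec.id] = str(rec.seq)
        data[locus] = seqs
    return MultiLocusAlignment(list(paths.keys()), data)


def write_multilocus_fasta(
    alignment: MultiLocusAlignment, directory: str | Path
) -> dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {}
    for locus in alignment.loci:
        path = directory / f"{locus}.fasta"
        records = [
            SeqRecord(Seq(seq), id=sid, description="")
            for sid, seq in sorted(alignment.data[locus].items())
        ]
        SeqIO.write(records, str(path), "fasta")
        out[locus] = path
    return out


# ------------------------------------------------------------- sample table
REQUIRED_SAMPLE_COLUMNS = ("latitude", "longitude", "region", "climate", "year")


class SampleTable:
    """Per-sample geography/region/climate metadata (index = sample ID)."""

    def __init__(self, frame: pd.DataFrame, regions: Sequence[str] = DEFAULT_REGIONS):
        missing = set(REQUIRED_SAMPLE_COLUMNS) - set(frame.columns)
        if missing:
            raise ValidationError(f"sample table missing columns: {sorted(missing)}")
        frame = frame.copy()
        frame["latitude"] = pd.to_numeric(frame["latitude"], errors="raise")
        frame["longitude"] = pd.to_numeric(frame["longitude"], errors="raise")
        frame["climate"] = pd.to_numeric(frame["climate"], errors="raise")
        frame["year"] = frame["year"].astype(int)
        if (frame["latitude"].abs() > 90).any():
            bad = frame.index[frame["latitude"].abs() > 90].tolist()
            raise ValidationError(f"latitude out of [-90, 90] for samples {bad}")
        if (frame["longitude"].abs() > 180).any():
            bad = frame.index[frame["longitude"].abs() > 180].tolist()
            raise ValidationError(f"longitude out of [-180, 180] for samples {bad}")
        unknown = set(frame["region"]) - set(regions)
        if unknown:
            raise ValidationError(
                f"unknown regions {sorted(unknown)}; configured set is {list(regions)}"
            )
        self.frame = frame
        self.regions = tuple(regions)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, ids: Iterable[str]) -> "SampleTable":
        return SampleTable(self.frame.loc[list(ids)], self.regions)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index_label="id")


def read_sample_table(
    path: str | Path, regions: Sequence[str] = DEFAULT_REGIONS
) -> SampleTable:
    try:
        frame = pd.read_csv(path, index_col="id")
    except ValueError as exc:
        raise ValidationError(f"cannot read sample table {path}: {exc}") from exc
    try:
        return SampleTable(frame, regions)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"bad values in sample table {path}: {exc}") from exc


# --------------------------------------------------------- distance matrices
class DistanceMatrix:
    """Labelled symmetric matrix with zero diagonal; the common currency of
    Mantel/ParaFit/PACo."""

    SYMMETRY_TOL = 1e-9

    def __init__(self, labels: Sequence[str], values, kind: str = "generic"):
        labels = list(labels)
        values = np.asarray(values, dtype=float)
        if len(labels) < 2:
            raise ValidationError("distance matrix needs at least 2 labels")
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate labels in distance matrix")
        if values.shape != (len(labels), len(labels)):
            raise ValidationError(
                f"matrix shape {values.shape} does not match {len(labels)} labels"
            )
        if not np.all(np.isfinite(values)):
            raise ValidationError("non-finite entries in distance matrix")
        if np.any(values < 0):
            raise ValidationError("negative entries in distance matrix")
        if np.max(np.abs(values - values.T)) > self.SYMMETRY_TOL:
            raise ValidationError("matrix is not symmetric within 1e-9")
        if np.max(np.abs(np.diag(values))) > self.SYMMETRY_TOL:
            raise ValidationError("matrix diagonal is not zero")
        self.labels = labels
        self.values = 0.5 * (values + values.T)
        np.fill_diagonal(self.values, 0.0)
        self.kind = kind
        self._index = {l: i for i, l in enumerate(labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self._index[l] for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.kind)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries, row-major (scipy 'condensed' order)."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, kind: str = "generic") -> "DistanceMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(list(frame.columns), frame.values, kind)


class AssociationMatrix:
    """Binary host-parasite links: rows = parasites, columns = hosts."""

    def __init__(self, parasites: Sequence[str], hosts: Sequence[str], links):
        self.parasites = list(parasites)
        self.hosts = list(hosts)
        links = np.asarray(links)
        if links.shape != (len(self.parasites), len(self.hosts)):
            raise ValidationError("association shape does not match labels")
        if not np.isin(links, (0, 1)).all():
            raise ValidationError("association entries must be 0/1")
        links = links.astype(int)
        if (links.sum(axis=1) == 0).any():
            empty = [p for p, s in zip(self.parasites, links.sum(axis=1)) if s == 0]
            raise ValidationError(f"parasites with no host link: {empty}")
        if (links.sum(axis=0) == 0).any():
            empty = [h for h, s in zip(self.hosts, links.sum(axis=0)) if s == 0]
            raise ValidationError(f"hosts with no parasite link: {empty}")
        self.links = links

    @property
    def link_pairs(self) -> list[tuple[str, str]]:
        rows, cols = np.nonzero(self.links)
        return [(self.parasites[i], self.hosts[j]) for i, j in zip(rows, cols)]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.links, index=self.parasites, columns=self.hosts).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AssociationMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(list(frame.index), list(frame.columns), frame.values)


# ---------------------------------------------------------------- cost raster
@dataclass
class CostRaster:
    """Plain-text cost grid for least-cost-path resistance distances.

    ``origin`` is the (lat, lon) of the *lower-left* cell center; rows are
    stored north-to-south as in the text format. ``math.inf`` marks barriers.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin: tuple[float, float]
    costs: np.ndarray = field(repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        self.costs = np.asarray(self.costs, dtype=float)
        if self.costs.shape != (self.n_rows, self.n_cols):
            raise ValidationError("raster costs shape mismatch")
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValidationError("raster must be at least 2x2")
        finite = self.costs[np.isfinite(self.costs)]
        if np.any(finite < 0):
            raise ValidationError("raster costs must be non-negative")

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lat, lon) of a cell center; row 0 is the northernmost row."""
        lat0, lon0 = self.origin
        lat = lat0 + (self.n_rows - 1 - row) * self.cell_size
        lon = lon0 + col * self.cell_size
        return lat, lon

    def cell_of(self, lat: float, lon: float) -> tuple[int, int]:
        lat0, lon0 = self.origin
        col = round((lon - lon0) / self.cell_size)
        row = self.n_rows - 1 - round((lat - lat0) / self.cell_size)
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValidationError(f"point ({lat}, {lon}) falls outside the raster")
        return row, col

    def to_text(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"ncols {self.n_cols}\n")
            fh.write(f"nrows {self.n_rows}\n")
            fh.write(f"yllcenter {self.origin[0]}\n")
            fh.write(f"xllcenter {self.origin[1]}\n")
            fh.write(f"cellsize {self.cell_size}\n")
            for row in self.costs:
                fh.write(" ".join("inf" if math.isinf(v) else f"{v:g}" for v in row))
                fh.write("\n")

    @classmethod
    def from_text(cls, path: str | Path) -> "CostRaster":
        with open(path) as fh:
            header = {}
            for _ in range(5):
                key, value = fh.readline().split()
                header[key.lower()] = float(value)
            rows = [
                [float(tok) for tok in line.split()]
                for line in fh
                if line.strip()
            ]
        return cls(
            n_rows=int(header["nrows"]),
            n_cols=int(header["ncols"]),
            cell_size=header["cellsize"],
            origin=(header["yllcenter"], header["xllcenter"]),
            costs=np.array(rows, dtype=float),
        )
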