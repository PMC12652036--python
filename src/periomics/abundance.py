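"""Species-level abundance profiles, microbial biomass and alpha diversity.

The shotgun profiler emits relative abundances (percent of classified reads
per sample).  Because the extracted DNA contains both human and microbial
material, microbial biomass is reconstructed in two steps: the sample's
microbial DNA is the total purified DNA times the fraction of reads mapping
to microbial genomes, and each species' absolute abundance (ng) is its
relative abundance times that microbial DNA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceMatrix",
    "BiomassMatrix",
    "read_metaphlan_table",
    "write_metaphlan_table",
    "microbial_dna",
    "absolute_abundance",
    "shannon_diversity",
    "observed_species",
    "prevalence_filter",
]

_SUM_TOL = 1e-6


@dataclass
class AbundanceMatrix:
    """Species x samples relative abundances (percent) with DNA metadata.

    Parameters
    ----------
    relative : DataFrame
        Rows are species (terminal species names, underscores preserved),
        columns are sample ids, values are percentages in [0, 100].
    sample_metadata : DataFrame, optional
        Indexed by sample id with columns ``total_dna_ng`` (>= 0) and
        ``microbial_read_fraction`` (in [0, 1]).  Required for biomass.
    """

    relative: pd.DataFrame
    sample_metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        rel = self.relative
        if rel.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if rel.index.duplicated().any():
            dups = rel.index[rel.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate species: {dups}")
        vals = rel.to_numpy(dtype=float)
        if (vals < 0).any():
            raise ValueError("relative abundances must be non-negative")
        sums = vals.sum(axis=0)
        if (sums > 100.0 + 1e-6 + 1e-9 * np.abs(sums)).any():
            bad = rel.columns[sums > 100.0 + 1e-6][:3].tolist()
            raise ValueError(f"species-level sums exceed 100% for samples {bad}")

    @property
    def species(self) -> pd.Index:
        return self.relative.index

    @property
    def samples(self) -> pd.Index:
        return self.relative.columns

    def microbial_dna(self) -> pd.Series:
        """Microbial DNA (ng) per sample: total DNA x microbial read fraction."""
        meta = self._require_metadata(self.samples)
        return pd.Series(
            microbial_dna(
                meta["total_dna_ng"].to_numpy(float),
                meta["microbial_read_fraction"].to_numpy(float),
            ),
            index=self.samples,
            name="microbial_dna_ng",
        )

    def _require_metadata(self, samples: pd.Index) -> pd.DataFrame:
        if self.sample_metadata is None:
            raise ValueError("sample metadata (DNA amounts) not provided")
        missing = samples.difference(self.sample_metadata.index)
        if len(missing):
            raise ValueError(f"missing DNA metadata for samples: {missing.tolist()[:5]}")
        return self.sample_metadata.loc[samples]

    def to_biomass(self) -> "BiomassMatrix":
        return absolute_abundance(self)

    def shannon(self) -> pd.Series:
        """Shannon diversity H per sample (natural log)."""
        return self.relative.apply(lambda c: shannon_diversity(c.to_numpy(float)))

    def observed(self, threshold: float = 0.0) -> pd.Series:
        return self.relative.apply(
            lambda c: observed_species(c.to_numpy(float), threshold)
        )

    def filter_prevalence(self, min_prevalence: float = 0.10) -> "AbundanceMatrix":
        return prevalence_filter(self, min_prevalence)


@dataclass
class BiomassMatrix:
    """Species x samples absolute DNA amounts (ng)."""

    absolute: pd.DataFrame

    @property
    def species(self) -> pd.Index:
        return self.absolute.index

    @property
    def samples(self) -> pd.Index:
        return self.absolute.columns


def microbial_dna(total_dna_ng, microbial_read_fraction):
    """Microbial DNA (ng) = total purified DNA x fraction of microbial reads."""
    total = np.asarray(total_dna_ng, dtype=float)
    frac = np.asarray(microbial_read_fraction, dtype=float)
    if (total < 0).any():
        raise ValueError("total DNA must be non-negative")
    if ((frac < 0) | (frac > 1)).any():
        raise ValueError("microbial read fraction must lie in [0, 1]")
    out = total * frac
    return float(out) if out.ndim == 0 else out


def absolute_abundance(matrix: AbundanceMatrix) -> BiomassMatrix:
    """Per-species biomass: (relative percent / 100) x sample microbial DNA.

    Species-level percentages may sum to less than 100 (unclassified
    remainder); that unassigned DNA is simply not attributed to any species,
    so column sums equal microbial DNA x (species-level sum / 100).
    """
    dna = matrix.microbial_dna()
    absolute = matrix.relative.div(100.0).mul(dna, axis=1)
    return BiomassMatrix(absolute)


def shannon_diversity(relative_vector, base: float = math.e) -> float:
    """Shannon index H = -sum p_i log p_i over renormalized nonzero entries.

    Natural log by default; scale-invariant, so relative or absolute
    abundances give the same value.
    """
    v = np.asarray(relative_vector, dtype=float)
    if (v < 0).any():
        raise ValueError("abundances must be non-negative")
    total = v.sum()
    if total <= 0:
        raise ValueError("Shannon diversity undefined for an all-zero vector")
    p = v[v > 0] / total
    return float(-(p * (np.log(p) / math.log(base))).sum())


def observed_species(relative_vector, threshold: float = 0.0) -> int:
    """Count of species with abundance strictly above ``threshold``."""
    v = np.asarray(relative_vector, dtype=float)
    if (v < 0).any():
        raise ValueError("abundances must be non-negative")
    return int((v > threshold).sum())


def prevalence_filter(
    matrix: AbundanceMatrix, min_prevalence: float = 0.10
) -> AbundanceMatrix:
    """Keep species present (nonzero) in at least ``min_prevalence`` of samples.

    The boundary is inclusive and the required sample count is the ceiling of
    ``min_prevalence * n_samples``, so with 10 samples and 10% a single
    occurrence suffices.
    """
    if not 0.0 <= min_prevalence <= 1.0:
        raise ValueError("min_prevalence must lie in [0, 1]")
    n = matrix.relative.shape[1]
    required = math.ceil(min_prevalence * n)
    counts = (matrix.relative.to_numpy(float) > 0).sum(axis=1)
    keep = matrix.relative.index[counts >= required]
    return AbundanceMatrix(matrix.relative.loc[keep], matrix.sample_metadata)


# ---------------------------------------------------------------------------
# MetaPhlAn-style table I/O


def _species_from_clade(clade: str) -> str | None:
    """Terminal species name, or None if the clade is not species-terminal."""
    parts = clade.split("|")
    last = parts[-1]
    if last.startswith("s__") and len(last) > 3:
        return last[3:]
    return None


def read_metaphlan_table(
    path, sample_metadata: pd.DataFrame | None = None
) -> AbundanceMatrix:
    """Parse a profiler-style TSV (clade rows, sample columns, percent values).

    Only rows whose clade string terminates at species level (``s__`` with no
    finer rank) are retained.  Malformed rows raise with their line number.
    """
    path = Path(path)
    rows: dict[str, list[float]] = {}
    samples: list[str] | None = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if samples is None:
                header = line.lstrip("#").split("\t")
                samples = header[1:]
                if not samples:
                    raise ValueError(f"{path}:{lineno}: header has no sample columns")
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(samples) + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {len(samples) + 1} fields, got {len(fields)}"
                )
            species = _species_from_clade(fields[0])
            if species is None:
                continue
            try:
                values = [float(x) for x in fields[1:]]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric abundance") from exc
            if species in rows:
                raise ValueError(f"{path}:{lineno}: duplicate species {species!r}")
            rows[species] = values
    if samples is None:
        raise ValueError(f"{path}: empty file")
    rel = pd.DataFrame.from_dict(rows, orient="index", columns=samples, dtype=float)
    return AbundanceMatrix(rel, sample_metadata)


def write_metaphlan_table(matrix: AbundanceMatrix, path) -> None:
    """Write species rows as ``k__Bacteria|...|s__<name>`` clade strings."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#clade_name\t" + "\t".join(map(str, matrix.samples)) + "\n")
        for species, row in matrix.relative.iterrows():
            clade = f"k__Bacteria|s__{species}"
            fh.write(clade + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
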