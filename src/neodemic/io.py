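"""Readers/writers for the pipeline's file formats, run configuration and seeding.

Sequence panels live on disk as an aligned FASTA plus a metadata CSV
(``id,population,age_years_bp``); ages are stored in years BP so the files
stay comparable to radiocarbon dates, and are converted once to whole
generations (floored) on reading.  Haplogroup counts are plain CSV tables
with a leading ``population`` column.  Run configurations are YAML.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DEFAULT_GENERATION_TIME = 25.0  # years per generation

_NUC = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lower case


class AlignmentError(ValueError):
    """Sequences in a panel are not an equal-length alignment."""


class MetadataError(ValueError):
    """FASTA record ids and the metadata table do not match."""


class ValidationError(ValueError):
    """A table violates the format contract (e.g. negative counts)."""


@dataclass
class RunConfig:
    """Seed plus stage-specific parameter blocks for a pipeline run.

    Every random procedure in the package draws its generator from
    :meth:`rng`, so two runs with the same config are bit-reproducible.
    """

    seed: int = 0
    generation_time: float = DEFAULT_GENERATION_TIME
    outdir: str = "."
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be >= 0")

    def rng(self, *path: str | int) -> np.random.Generator:
        """Child generator for a named stage, derived from the run seed."""
        keys = [
            zlib.crc32(p.encode()) if isinstance(p, str) else int(p) for p in path
        ]
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=keys))

    def stage(self, name: str) -> dict:
        return dict(self.params.get(name, {}))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


@dataclass
class SequencePanel:
    """Aligned haploid sequences with population labels and sampling ages.

    ``seqs`` is an (n, L) uint8 array with A,C,G,T coded 0..3.  Ages are
    kept both in years BP (as on disk) and in whole generations.
    """

    ids: list[str]
    seqs: np.ndarray
    labels: list[str]
    ages_years: np.ndarray
    ages_gen: np.ndarray

    def __post_init__(self) -> None:
        self.seqs = np.asarray(self.seqs, dtype=np.uint8)
        self.ages_years = np.asarray(self.ages_years, dtype=float)
        self.ages_gen = np.asarray(self.ages_gen, dtype=int)
        n = len(self.ids)
        if not (self.seqs.shape[0] == len(self.labels) == n == len(self.ages_gen)):
            raise ValidationError("panel fields have inconsistent lengths")

    @property
    def n(self) -> int:
        return self.seqs.shape[0]

    @property
    def length(self) -> int:
        return self.seqs.shape[1]

    def subset(self, mask: np.ndarray) -> "SequencePanel":
        idx = np.flatnonzero(np.asarray(mask))
        return SequencePanel(
            ids=[self.ids[i] for i in idx],
            seqs=self.seqs[idx],
            labels=[self.labels[i] for i in idx],
            ages_years=self.ages_years[idx],
            ages_gen=self.ages_gen[idx],
        )

    def population(self, label: str) -> "SequencePanel":
        return self.subset(np.array([lab == label for lab in self.labels]))

    def sequences_as_strings(self) -> list[str]:
        return ["".join(chr(_NUC[c]) for c in row) for row in self.seqs]


def encode_sequences(strings: list[str]) -> np.ndarray:
    """Encode equal-length A/C/G/T strings as an (n, L) uint8 matrix."""
    lengths = {len(s) for s in strings}
    if len(lengths) > 1:
        raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
    raw = np.frombuffer("".join(strings).encode(), dtype=np.uint8)
    codes = _CODE[raw].reshape(len(strings), -1)
    if (codes == 255).any():
        raise ValidationError("non-ACGT character in sequence")
    return codes


def years_to_generations(years: np.ndarray, generation_time: float) -> np.ndarray:
    """Floor-convert ages in years BP to whole generations BP."""
    return np.floor(np.asarray(years, dtype=float) / generation_time).astype(int)


def read_sequence_panel(
    fasta_path: str | Path,
    metadata_path: str | Path,
    generation_time: float = DEFAULT_GENERATION_TIME,
) -> SequencePanel:
    """Read an aligned FASTA plus ``id,population,age_years_bp`` metadata.

    Records lacking metadata are rejected; ages are converted to whole
    generations with the configured generation time.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValidationError(f"no FASTA records in {fasta_path}")
    meta = pd.read_csv(metadata_path, dtype={"id": str})
    for col in ("id", "population", "age_years_bp"):
        if col not in meta.columns:
            raise MetadataError(f"metadata misses column {col!r}")
    meta = meta.set_index("id")
    ids = [r.id for r in records]
    missing = [i for i in ids if i not in meta.index]
    if missing:
        raise MetadataError(f"records without metadata: {missing[:5]}")
    seqs = encode_sequences([str(r.seq) for r in records])
    ages_years = meta.loc[ids, "age_years_bp"].to_numpy(dtype=float)
    return SequencePanel(
        ids=ids,
        seqs=seqs,
        labels=list(meta.loc[ids, "population"]),
        ages_years=ages_years,
        ages_gen=years_to_generations(ages_years, generation_time),
    )


def write_sequence_panel(
    panel: SequencePanel, fasta_path: str | Path, metadata_path: str | Path
) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="")
        for i, s in zip(panel.ids, panel.sequences_as_strings())
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    pd.DataFrame(
        {"id": panel.ids, "population": panel.labels, "age_years_bp": panel.ages_years}
    ).to_csv(metadata_path, index=False)


@dataclass
class HaplogroupCounts:
    """Population × haplogroup count matrix with derived sample sizes."""

    populations: list[str]
    haplogroups: list[str]
    counts: np.ndarray  # (P, K) non-negative ints

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.populations), len(self.haplogroups)):
            raise ValidationError("counts shape does not match labels")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValidationError("non-integer haplogroup count")
            counts = np.round(counts).astype(int)
        if (counts < 0).any():
            raise ValidationError("negative haplogroup count")
        self.counts = counts.astype(int)

    @property
    def sample_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def n_haplogroups(self) -> int:
        return len(self.haplogroups)

    def row(self, population: str) -> np.ndarray:
        return self.counts[self.populations.index(population)]


def read_haplogroup_counts(path: str | Path) -> HaplogroupCounts:
    """Read a CSV whose first column is the population label."""
    df = pd.read_csv(path)
    pop_col = df.columns[0]
    populations = [str(p) for p in df[pop_col]]
    haplogroups = [str(c) for c in df.columns[1:]]
    if not haplogroups:
        raise ValidationError("count table has no haplogroup columns")
    values = df[df.columns[1:]].to_numpy()
    return HaplogroupCounts(populations=populations, haplogroups=haplogroups, counts=values)


def write_haplogroup_counts(table: HaplogroupCounts, path: str | Path) -> None:
    df = pd.DataFrame(table.counts, columns=table.haplogroups)
    df.insert(0, "population", table.populations)
    df.to_csv(path, index=False)
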