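"""Diploid biallelic genotype container and its on-disk dialects.

The :class:`GenotypeMatrix` is the universal SNP container of the package:
an individuals × sites matrix of alternate-allele dosages (0, 1, 2, with -1
for missing), a site → RAD-locus map, and a population label per individual.
It round-trips through a minimal VCFv4.2 dialect (GT field only) and a TSV
genotype table (rows = individuals, columns = sites named ``locus:pos``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1
_ALLOWED_CODES = frozenset({-1, 0, 1, 2})


@dataclass
class GenotypeMatrix:
    """Individuals × sites matrix of alternate-allele dosages.

    Parameters
    ----------
    genotypes
        ``(n_individuals, n_sites)`` int8 array with entries in
        ``{0, 1, 2, -1}``; ``-1`` marks a missing genotype call.
    samples
        Individual identifiers, one per row.
    populations
        Population label per individual.
    site_loci
        Locus identifier per site (many sites may share a locus).
    site_pos
        1-based position of each site within its locus.
    locus_length
        Length of each RAD locus in bp.
    n_loci_assayed
        Total number of assayed loci, including loci that yielded no SNP.
        Defaults to the number of distinct loci present among the sites.
        Together with ``locus_length`` this defines the assayed sequence
        length ``L`` used to normalise per-site diversity statistics.
    """

    genotypes: np.ndarray
    samples: list[str]
    populations: np.ndarray
    site_loci: np.ndarray
    site_pos: np.ndarray
    locus_length: int = 51
    n_loci_assayed: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D individuals × sites array")
        self.populations = np.asarray(self.populations, dtype=object)
        self.site_loci = np.asarray(self.site_loci, dtype=object)
        self.site_pos = np.asarray(self.site_pos, dtype=int)
        n_ind, n_sites = self.genotypes.shape
        if len(self.samples) != n_ind:
            raise ValueError("samples length does not match genotype rows")
        if len(self.populations) != n_ind:
            raise ValueError("populations length does not match genotype rows")
        if len(self.site_loci) != n_sites or len(self.site_pos) != n_sites:
            raise ValueError("site annotation length does not match genotype columns")
        codes = set(np.unique(self.genotypes).tolist())
        if not codes <= _ALLOWED_CODES:
            raise ValueError(f"genotype codes outside {{0,1,2,-1}}: {sorted(codes - _ALLOWED_CODES)}")

    # ------------------------------------------------------------------ shape
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_loci(self) -> int:
        explicit = self.n_loci_assayed
        return explicit if explicit is not None else len(set(self.site_loci.tolist()))

    @property
    def L(self) -> int:
        """Total assayed sequence length in bp (loci × locus length)."""
        return self.n_loci * self.locus_length

    def subset_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.genotypes[:, index],
            list(self.samples),
            self.populations.copy(),
            self.site_loci[index],
            self.site_pos[index],
            locus_length=self.locus_length,
            n_loci_assayed=self.n_loci_assayed,
            metadata=dict(self.metadata),
        )

    def subset_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.genotypes[index],
            [self.samples[i] for i in np.atleast_1d(index)],
            self.populations[index],
            self.site_loci.copy(),
            self.site_pos.copy(),
            locus_length=self.locus_length,
            n_loci_assayed=self.n_loci_assayed,
            metadata=dict(self.metadata),
        )

    def population_index(self, label: str) -> np.ndarray:
        idx = np.flatnonzero(self.populations == label)
        if idx.size == 0:
            raise ValueError(f"no individuals labelled {label!r}")
        return idx

    # --------------------------------------------------------------------- IO
    def to_vcf(self, path) -> None:
        """Write the minimal VCFv4.2 dialect (GT only, ``./.`` for missing)."""
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##source=rangeedge\n##rangeedge_locus_length={self.locus_length}\n")
            fh.write(f"##rangeedge_n_loci_assayed={self.n_loci}\n")
            for locus in dict.fromkeys(self.site_loci.tolist()):
                fh.write(f"##contig=<ID={locus},length={self.locus_length}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
            fh.write("\t".join(self.samples) + "\n")
            for s in range(self.n_sites):
                row = self.genotypes[:, s]
                fields = [
                    str(self.site_loci[s]),
                    str(self.site_pos[s]),
                    f"{self.site_loci[s]}:{self.site_pos[s]}",
                    "A",
                    "T",
                    ".",
                    "PASS",
                    ".",
                    "GT",
                ]
                fields.extend(gt_strings[int(g)] for g in row)
                fh.write("\t".join(fields) + "\n")

    def to_tsv(self, path) -> None:
        """Write the TSV dialect: one row per individual, ``locus:pos`` columns."""
        with open(path, "w") as fh:
            header = ["sample", "population"] + [
                f"{l}:{p}" for l, p in zip(self.site_loci, self.site_pos)
            ]
            fh.write("\t".join(header) + "\n")
            fh.write(f"#locus_length={self.locus_length}\tn_loci_assayed={self.n_loci}\n")
            for i, name in enumerate(self.samples):
                vals = [name, str(self.populations[i])]
                vals.extend(str(int(g)) for g in self.genotypes[i])
                fh.write("\t".join(vals) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            meta_line = fh.readline().strip()
            locus_length, n_loci = 51, None
            if meta_line.startswith("#"):
                for tok in meta_line.lstrip("#").split("\t"):
                    key, _, val = tok.partition("=")
                    if key == "locus_length":
                        locus_length = int(val)
                    elif key == "n_loci_assayed":
                        n_loci = int(val)
            site_names = header[2:]
            loci, pos = [], []
            for name in site_names:
                locus, _, p = name.rpartition(":")
                loci.append(locus)
                pos.append(int(p))
            samples, pops, rows = [], [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                samples.append(parts[0])
                pops.append(parts[1])
                rows.append([int(v) for v in parts[2:]])
        return cls(
            np.array(rows, dtype=np.int8),
            samples,
            np.array(pops, dtype=object),
            np.array(loci, dtype=object),
            np.array(pos, dtype=int),
            locus_length=locus_length,
            n_loci_assayed=n_loci,
        )
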