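"""PLINK .ped/.map text export for simulated replicate datasets.

Lets a simulated dataset be fed to standard association toolchains.  The
additive genotype g (minor-allele count) is written as an allele pair with
``A`` the minor and ``G`` the major allele: g=0 -> "G G", g=1 -> "A G",
g=2 -> "A A".  Binary phenotypes use PLINK's 1=control / 2=case coding;
quantitative phenotypes are written as fixed 6-decimal reals.  Output is
byte-stable for a given dataset.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .power import ReplicateDataset

__all__ = ["export_plink", "read_ped"]

_ALLELES = {0: "G G", 1: "A G", 2: "A A"}


def export_plink(dataset: ReplicateDataset, prefix) -> tuple[Path, Path]:
    """Write ``<prefix>.ped`` and ``<prefix>.map`` for a replicate dataset.

    The ped phenotype column holds the signal phenotype (PLINK ped carries a
    single phenotype).  Returns the two paths written.
    """
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")

    n, n_snps = dataset.genotypes.shape
    pheno = dataset.phenotypes[:, dataset.signal_phenotype]
    lines = []
    for i in range(n):
        if dataset.trait == "binary":
            ph = str(int(pheno[i]) + 1)  # 1=control, 2=case
        else:
            ph = f"{float(pheno[i]):.6f}"
        fields = [f"FAM{i + 1}", f"IND{i + 1}", "0", "0", "0", ph]
        fields.extend(_ALLELES[int(dataset.genotypes[i, s])] for s in range(n_snps))
        lines.append(" ".join(fields))
    ped_path.write_text("\n".join(lines) + "\n")

    labels = dataset.snp_labels or tuple(f"snp{s + 1}" for s in range(n_snps))
    map_lines = [
        f"1 {labels[s]} 0 {(s + 1) * 10000}" for s in range(n_snps)
    ]
    map_path.write_text("\n".join(map_lines) + "\n")
    return ped_path, map_path


def read_ped(ped_path, map_path):
    """Round-trip reader for the exported .ped/.map pair.

    Returns (genotypes int8 array (n x n_snps), phenotype float array,
    snp_labels).  Intended for format-conformance checks.
    """
    snp_labels = []
    with open(map_path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"malformed .map line: {line!r}")
            snp_labels.append(parts[1])
    n_snps = len(snp_labels)
    genotypes = []
    phenos = []
    rev = {v: k for k, v in _ALLELES.items()}
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) != 6 + 2 * n_snps:
                raise ValueError(
                    f"ped line has {len(parts)} fields, expected {6 + 2 * n_snps}"
                )
            phenos.append(float(parts[5]))
            row = []
            for s in range(n_snps):
                pair = " ".join(sorted(parts[6 + 2 * s: 8 + 2 * s], key="AG".index))
                row.append(rev[pair])
            genotypes.append(row)
    return np.array(genotypes, dtype=np.int8), np.array(phenos), snp_labels
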