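"""Core containers and I/O for case-control genotype data.

Genotypes are stored as minor-allele counts (0/1/2 copies of the allele
that is less frequent in the pooled case+control sample) for ``n``
individuals by ``M`` variants, with phenotype labels coded +1 for cases and
-1 for controls to match the SVM sign convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_CASE_CODES = {"case", "1", "affected"}
_CTRL_CODES = {"control", "0", "unaffected"}


@dataclass
class GenotypeDataset:
    """Minor-allele count matrix with case/control labels.

    Parameters
    ----------
    counts
        Integer matrix of shape (n individuals, M variants) with entries in
        {0, 1, 2}: copies of the minor (targeted) allele.
    labels
        Vector of n phenotype labels, +1 for cases and -1 for controls.
    variant_ids
        M unique variant identifiers.
    sample_ids
        Optional n sample identifiers (generated if omitted).
    """

    counts: np.ndarray
    labels: np.ndarray
    variant_ids: list[str]
    sample_ids: list[str] | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.variant_ids = [str(v) for v in self.variant_ids]
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if not np.isin(self.counts, (0, 1, 2)).all():
            raise ValueError("genotype counts must be 0, 1 or 2")
        self.counts = self.counts.astype(np.int8)
        if self.labels.shape[0] != self.counts.shape[0]:
            raise ValueError("labels length does not match number of rows")
        if not np.isin(self.labels, (-1, 1)).all():
            raise ValueError("labels must be +1 (case) or -1 (control)")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("need at least one case and one control")
        if len(self.variant_ids) != self.counts.shape[1]:
            raise ValueError("variant_ids length does not match columns")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("variant_ids must be unique")
        if self.sample_ids is None:
            self.sample_ids = [f"S{k + 1:05d}" for k in range(self.n)]
        elif len(self.sample_ids) != self.n:
            raise ValueError("sample_ids length does not match rows")

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def n_variants(self) -> int:
        return self.counts.shape[1]

    @property
    def n1(self) -> int:
        """Number of cases."""
        return int(np.sum(self.labels == 1))

    @property
    def n2(self) -> int:
        """Number of controls."""
        return int(np.sum(self.labels == -1))

    def subset_variants(self, variant_ids) -> "GenotypeDataset":
        idx = [self.variant_ids.index(v) for v in variant_ids]
        return GenotypeDataset(self.counts[:, idx], self.labels.copy(),
                               [self.variant_ids[i] for i in idx],
                               list(self.sample_ids))


@dataclass
class VariantSummary:
    """Per-variant minor-allele counts, direction category and weight."""

    variant_id: str
    m_case: int
    m_ctrl: int
    category: str | None = None  # "risk" or "nonrisk"
    weight: float | None = None

    @property
    def m_total(self) -> int:
        return self.m_case + self.m_ctrl


def summarize_variants(data: GenotypeDataset) -> list[VariantSummary]:
    """Sum the minor alleles of every variant over cases and over controls.

    Categories and weights are left unset; conservation holds by
    construction: ``m_case + m_ctrl`` equals the column sum.
    """
    case_mask = data.labels == 1
    m_case = data.counts[case_mask].sum(axis=0)
    m_ctrl = data.counts[~case_mask].sum(axis=0)
    return [VariantSummary(v, int(mc), int(mu))
            for v, mc, mu in zip(data.variant_ids, m_case, m_ctrl)]


def drop_monomorphic(data: GenotypeDataset):
    """Remove variants with no minor allele in the sample.

    Their weight is undefined (zero total mutant count), so they carry no
    information for the collapsed covariates.  Returns the filtered dataset
    and the list of dropped variant ids.
    """
    colsum = data.counts.sum(axis=0)
    keep = colsum > 0
    dropped = [v for v, k in zip(data.variant_ids, keep) if not k]
    if dropped:
        logger.warning("dropping %d monomorphic variant(s): %s",
                       len(dropped), ", ".join(dropped))
        data = GenotypeDataset(data.counts[:, keep], data.labels,
                               [v for v, k in zip(data.variant_ids, keep) if k],
                               list(data.sample_ids))
    return data, dropped


def _read_phenotypes(phenotype_path) -> pd.Series:
    pheno = pd.read_csv(phenotype_path, sep="\t", dtype=str)
    if list(pheno.columns[:2]) != ["sample_id", "status"]:
        raise ValueError("phenotype file must have header "
                         "'sample_id<TAB>status'")
    labels = {}
    for sid, status in zip(pheno["sample_id"], pheno["status"]):
        s = str(status).strip().lower()
        if s in _CASE_CODES:
            labels[sid] = 1
        elif s in _CTRL_CODES:
            labels[sid] = -1
        else:
            raise ValueError(f"unrecognised status {status!r} for {sid}")
    if len(labels) != len(pheno):
        raise ValueError("duplicate sample ids in phenotype file")
    return pd.Series(labels)


def read_genotypes(vcf_path, phenotype_path, missing_policy="error",
                   split_multiallelic=False) -> GenotypeDataset:
    """Read a VCF and a phenotype TSV into a :class:`GenotypeDataset`.

    The counted (minor) allele is the one less frequent in the pooled
    sample; at a frequency tie the ALT allele is counted.  Sample order
    follows the phenotype file.

    Parameters
    ----------
    missing_policy
        ``"error"`` (default) rejects missing genotypes; ``"impute_zero"``
        treats them as homozygous for the untargeted allele.
    split_multiallelic
        Decompose multi-allelic records into one variant per ALT allele;
        otherwise such records raise an error.
    """
    from cyvcf2 import VCF

    if missing_policy not in ("error", "impute_zero"):
        raise ValueError("missing_policy must be 'error' or 'impute_zero'")
    pheno = _read_phenotypes(phenotype_path)
    vcf = VCF(str(vcf_path))
    vcf_samples = list(vcf.samples)
    missing_samples = [s for s in pheno.index if s not in vcf_samples]
    if missing_samples:
        raise ValueError("sample id(s) in phenotype file but not in VCF: "
                         + ", ".join(missing_samples))
    order = [vcf_samples.index(s) for s in pheno.index]

    columns = []
    ids = []
    for rec_no, variant in enumerate(vcf):
        alts = variant.ALT
        if len(alts) != 1:
            if not split_multiallelic:
                raise ValueError(
                    f"multi-allelic record at {variant.CHROM}:{variant.POS}; "
                    "rerun with split_multiallelic=True")
        gts = variant.genotypes  # [allele0, allele1, phased] per sample
        base_id = variant.ID or f"{variant.CHROM}:{variant.POS}"
        for ai in range(1, len(alts) + 1):
            alt_count = np.zeros(len(pheno), dtype=np.int64)
            called = np.full(len(pheno), 2, dtype=np.int64)
            for out_k, vcf_k in enumerate(order):
                a0, a1 = gts[vcf_k][0], gts[vcf_k][1]
                c = 0
                nc = 0
                for a in (a0, a1):
                    if a < 0:
                        nc += 1
                    elif a == ai:
                        c += 1
                if nc:
                    if missing_policy == "error":
                        raise ValueError(
                            f"missing genotype for sample "
                            f"{pheno.index[out_k]} at {base_id}")
                    called[out_k] -= nc
                alt_count[out_k] = c
            total_called = int(called.sum())
            if total_called == 0:
                raise ValueError(f"no called genotypes at {base_id}")
            alt_freq = alt_count.sum() / total_called
            if alt_freq <= 0.5:
                col = alt_count
            else:  # ALT is the major allele: count the other allele
                col = called - alt_count
            columns.append(col.astype(np.int8))
            vid = base_id if len(alts) == 1 else f"{base_id}_alt{ai}"
            ids.append(vid)
    if not columns:
        raise ValueError("VCF contains no usable variant records")
    counts = np.stack(columns, axis=1)
    return GenotypeDataset(counts, pheno.to_numpy(), ids, list(pheno.index))


def write_genotypes(data: GenotypeDataset, vcf_path, phenotype_path) -> None:
    """Write a minimal VCF 4.2 plus phenotype TSV.

    Counts are encoded as copies of the ALT allele.  Reading the pair back
    with :func:`read_genotypes` round-trips counts and labels exactly as
    long as every column's allele frequency is at most 0.5 (the invariant
    of minor-allele counts); a column above 0.5 triggers a warning because
    the reader would re-polarise it.
    """
    freqs = data.counts.sum(axis=0) / (2 * data.n)
    if (freqs > 0.5).any():
        warnings.warn("column(s) with counted-allele frequency > 0.5: "
                      "a reader will flip their polarity")
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(data.sample_ids) + "\n")
        for j, vid in enumerate(data.variant_ids):
            gts = "\t".join(gt_map[int(c)] for c in data.counts[:, j])
            fh.write(f"1\t{j + 1}\t{vid}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")
    write_phenotypes(data, phenotype_path)


def write_phenotypes(data: GenotypeDataset, phenotype_path) -> None:
    with open(phenotype_path, "w") as fh:
        fh.write("sample_id\tstatus\n")
        for sid, lab in zip(data.sample_ids, data.labels):
            fh.write(f"{sid}\t{'case' if lab == 1 else 'control'}\n")


def write_matrix_tsv(data: GenotypeDataset, path) -> None:
    """Internal plain-matrix fixture format: variants x samples TSV."""
    df = pd.DataFrame(data.counts.T, index=data.variant_ids,
                      columns=data.sample_ids)
    df.index.name = "variant_id"
    df.to_csv(path, sep="\t")


def read_matrix_tsv(path, phenotype_path) -> GenotypeDataset:
    df = pd.read_csv(path, sep="\t", index_col="variant_id")
    pheno = _read_phenotypes(phenotype_path)
    missing = [s for s in pheno.index if s not in df.columns]
    if missing:
        raise ValueError("sample id(s) in phenotype file but not in matrix: "
                         + ", ".join(missing))
    counts = df[list(pheno.index)].to_numpy().T
    return GenotypeDataset(counts, pheno.to_numpy(),
                           list(df.index), list(pheno.index))
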