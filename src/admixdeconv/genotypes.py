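"""Dosage-coded genotype container with VCF round-trip and SNP statistics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam


@dataclass
class GenotypeMatrix:
    """SNP dosages (variants x samples) plus variant metadata.

    ``dosage`` counts copies of the alt allele (0..2).  ``freq_afr`` /
    ``freq_eur`` are alt-allele frequencies in the two ancestral reference
    populations when known.  ``haplotypes`` (variants x 2*samples, alt allele
    indicator, sample s owning columns 2s and 2s+1) is retained by the
    simulator so that local-ancestry scoring can be exercised.
    """

    variant_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray  # 1-based
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray
    sample_ids: list[str]
    freq_afr: np.ndarray | None = None
    freq_eur: np.ndarray | None = None
    haplotypes: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.variant_id = np.asarray(self.variant_id)
        self.pos = np.asarray(self.pos, int)
        self.dosage = np.asarray(self.dosage, float)
        if self.dosage.shape != (len(self.variant_id), len(self.sample_ids)):
            raise ValueError("dosage shape does not match variants x samples")
        if len(np.unique(self.variant_id)) != len(self.variant_id):
            raise ValueError("variant ids must be unique")

    @property
    def n_variants(self) -> int:
        return len(self.variant_id)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def maf(self) -> np.ndarray:
        f = self.dosage.mean(axis=1) / 2.0
        return np.minimum(f, 1.0 - f)

    def subset(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = np.zeros(self.n_variants, bool)
            idx[mask] = True
            mask = idx
        return GenotypeMatrix(
            variant_id=self.variant_id[mask],
            chrom=np.asarray(self.chrom)[mask],
            pos=self.pos[mask],
            ref=np.asarray(self.ref)[mask],
            alt=np.asarray(self.alt)[mask],
            dosage=self.dosage[mask],
            sample_ids=self.sample_ids,
            freq_afr=None if self.freq_afr is None else np.asarray(self.freq_afr)[mask],
            freq_eur=None if self.freq_eur is None else np.asarray(self.freq_eur)[mask],
            haplotypes=None if self.haplotypes is None else self.haplotypes[mask],
        )

    def window(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of variants with 1-based pos in [start, end] on chrom."""
        return np.where(
            (np.asarray(self.chrom) == chrom) & (self.pos >= start) & (self.pos <= end)
        )[0]

    def variants_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "variant_id": self.variant_id,
                "chrom": self.chrom,
                "pos": self.pos,
                "ref": self.ref,
                "alt": self.alt,
            }
        )
        if self.freq_afr is not None:
            df["freq_afr"] = self.freq_afr
            df["freq_eur"] = self.freq_eur
        return df

    # ------------------------------------------------------------------ VCF
    def write_vcf(self, path: str) -> None:
        """Write an uncompressed VCF with GT (if haplotypes known) and DS."""
        header = pysam.VariantHeader()
        chroms = pd.unique(np.asarray(self.chrom))
        for c in chroms:
            end = int(self.pos[np.asarray(self.chrom) == c].max()) + 1
            header.contigs.add(str(c), length=end)
        header.formats.add("GT", 1, "String", "Genotype")
        header.formats.add("DS", 1, "Float", "Alt allele dosage")
        for s in self.sample_ids:
            header.add_sample(str(s))
        with pysam.VariantFile(path, "w", header=header) as out:
            for i in range(self.n_variants):
                rec = out.new_record(
                    contig=str(np.asarray(self.chrom)[i]),
                    start=int(self.pos[i]) - 1,
                    stop=int(self.pos[i]),
                    alleles=(str(np.asarray(self.ref)[i]), str(np.asarray(self.alt)[i])),
                    id=str(self.variant_id[i]),
                )
                for s, name in enumerate(self.sample_ids):
                    smp = rec.samples[str(name)]
                    if self.haplotypes is not None:
                        smp["GT"] = (
                            int(self.haplotypes[i, 2 * s]),
                            int(self.haplotypes[i, 2 * s + 1]),
                        )
                        smp.phased = True
                    else:
                        d = int(round(self.dosage[i, s]))
                        smp["GT"] = (1, 1) if d == 2 else ((0, 1) if d == 1 else (0, 0))
                    smp["DS"] = float(self.dosage[i, s])
                out.write(rec)

    @classmethod
    def read_vcf(cls, path: str) -> "GenotypeMatrix":
        """Load dosages from a VCF; prefers DS, falls back to GT allele count."""
        with pysam.VariantFile(path) as vf:
            samples = list(vf.header.samples)
            vid, chrom, pos, ref, alt, rows, haps = [], [], [], [], [], [], []
            has_gt = True
            for rec in vf:
                vid.append(rec.id or f"{rec.chrom}:{rec.pos}")
                chrom.append(rec.chrom)
                pos.append(rec.pos)
                ref.append(rec.ref)
                alt.append(rec.alts[0])
                row, hap = [], []
                for s in samples:
                    smp = rec.samples[s]
                    gt = smp.get("GT")
                    if "DS" in smp and smp["DS"] is not None:
                        row.append(float(smp["DS"]))
                    else:
                        row.append(float(sum(a or 0 for a in gt)))
                    if gt is None or any(a is None for a in gt):
                        has_gt = False
                        hap.extend([0, 0])
                    else:
                        hap.extend(int(a) for a in gt)
                rows.append(row)
                haps.append(hap)
        return cls(
            variant_id=np.array(vid),
            chrom=np.array(chrom),
            pos=np.array(pos, int),
            ref=np.array(ref),
            alt=np.array(alt),
            dosage=np.array(rows, float),
            sample_ids=[str(s) for s in samples],
            haplotypes=np.array(haps, np.int8) if has_gt else None,
        )


def hwe_exact_pvalue(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact conditional Hardy-Weinberg test (two-sided, no mid-p).

    P is the total probability, under the exact conditional distribution of
    heterozygote counts given allele counts, of all outcomes no more likely
    than the observed one.
    """
    n_het, n_hom1, n_hom2 = int(n_het), int(n_hom1), int(n_hom2)
    rare = 2 * min(n_hom1, n_hom2) + n_het
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    # enumerate heterozygote counts with the parity of the rare allele count
    het_values = np.arange(rare % 2, rare + 1, 2)
    logp = np.zeros(len(het_values))
    # unnormalized log-probabilities: P(het) ∝ 2^het / (het! hom_r! hom_c!)
    from scipy.special import gammaln

    for k, h in enumerate(het_values):
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        logp[k] = h * np.log(2.0) - gammaln(h + 1) - gammaln(hom_r + 1) - gammaln(hom_c + 1)
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = np.where(het_values == n_het)[0][0]
    return float(np.minimum(p[p <= p[obs] * (1 + 1e-12)].sum(), 1.0))


def hwe_pvalues_from_dosage(dosage: np.ndarray) -> np.ndarray:
    """HWE exact p per variant from hard (rounded) dosages."""
    d = np.rint(np.asarray(dosage))
    out = np.empty(d.shape[0])
    for i in range(d.shape[0]):
        out[i] = hwe_exact_pvalue(
            int((d[i] == 1).sum()), int((d[i] == 0).sum()), int((d[i] == 2).sum())
        )
    return out
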