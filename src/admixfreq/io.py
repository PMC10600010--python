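"""Readers and writers for the formats the pipeline touches.

Supported formats: phased VCF 4.2, RFMix-v2-style ``msp.tsv`` /
``fb.tsv``, hap-IBD-style IBD/ROH TSV (headerless: sample1 hap1 sample2
hap2 chrom start end length_cM), PLINK-style genetic maps (chrom, id,
cM, bp) and a sites-only frequency VCF carrying the ancestry-resolved
INFO keys.

Readers validate coordinate order and probability normalization;
writers always emit sorted records.  Only biallelic records are
accepted — multiallelics must be split upstream.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .types import (
    IBD_COLUMNS,
    MISSING,
    AncestryFrequencyTable,
    GeneticMap,
    IBDSegmentSet,
    LocalAncestryField,
    PhasedHaplotypeSet,
)


class FormatError(ValueError):
    """A file violated the format contract."""


# ---------------------------------------------------------------------------
# phased VCF


def read_phased_vcf(
    path: str | Path,
    allow_unphased: bool = False,
    on_multiallelic: str = "error",
) -> PhasedHaplotypeSet:
    """Read a phased, biallelic, single-chromosome VCF into an allele matrix.

    Unphased het genotypes raise unless ``allow_unphased`` is set (the
    caller is then responsible for applying a singleton phase policy).
    ``on_multiallelic`` is "error" or "skip" (skip warns per record).
    """
    if on_multiallelic not in ("error", "skip"):
        raise ValueError("on_multiallelic must be 'error' or 'skip'")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    positions, ref, alt, rows = [], [], [], []
    chrom = None
    last_pos = -1
    for v in vcf:
        if len(v.ALT) != 1:
            if on_multiallelic == "error":
                raise FormatError(f"multiallelic record at {v.CHROM}:{v.POS}")
            warnings.warn(f"skipping multiallelic record at {v.CHROM}:{v.POS}")
            continue
        if chrom is None:
            chrom = v.CHROM
        elif v.CHROM != chrom:
            raise FormatError("expected a single-chromosome VCF")
        if v.POS <= last_pos:
            raise FormatError(f"positions not strictly increasing at {v.CHROM}:{v.POS}")
        last_pos = v.POS
        g = v.genotype.array()  # (n, 3): allele1, allele2, phased flag
        het = g[:, 0] != g[:, 1]
        nonmissing = (g[:, 0] >= 0) & (g[:, 1] >= 0)
        unphased = nonmissing & het & (g[:, 2] == 0)
        if unphased.any() and not allow_unphased:
            bad = samples[int(np.flatnonzero(unphased)[0])]
            raise FormatError(
                f"unphased genotype at {v.CHROM}:{v.POS} (sample {bad}); "
                "rerun with allow_unphased to accept"
            )
        a = g[:, :2].astype(np.int8)
        a[a < 0] = MISSING
        positions.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        rows.append(a)
    vcf.close()
    if not rows:
        raise FormatError(f"no biallelic records in {path}")
    alleles = np.stack(rows, axis=-1)  # (n, 2, m)
    return PhasedHaplotypeSet(samples, chrom, np.array(positions), ref, alt, alleles)


def write_phased_vcf(haps: PhasedHaplotypeSet, path: str | Path) -> None:
    """Write a phased biallelic VCF 4.2 ('|' separated GT)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={haps.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(haps.samples) + "\n")
        for m in range(haps.n_variants):
            gts = []
            for i in range(haps.n_samples):
                a = [
                    "." if haps.alleles[i, j, m] == MISSING else str(haps.alleles[i, j, m])
                    for j in (0, 1)
                ]
                gts.append("|".join(a))
            fh.write(
                f"{haps.chrom}\t{haps.positions[m]}\t.\t{haps.ref[m]}\t{haps.alt[m]}"
                f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# RFMix v2 msp / fb


def write_msp(lai: LocalAncestryField, path: str | Path, chrom: str = "1") -> None:
    """Write hard calls as an RFMix-v2-style msp.tsv.

    Each anchor becomes one window whose bp midpoint is the anchor, so a
    read-back through :func:`read_local_ancestry` reproduces the anchors.
    """
    anchors = lai.anchors
    calls = lai.probs.argmax(axis=-1)  # (n, 2, A)
    n, _, A = calls.shape
    if A > 1:
        gaps = np.diff(anchors)
        left = np.concatenate(([gaps[0]], gaps))
        right = np.concatenate((gaps, [gaps[-1]]))
        half = np.minimum(left, right) // 2
        half = np.maximum(half, 1)
    else:
        half = np.array([1])
    spos = anchors - half
    epos = anchors + half
    codes = "\t".join(f"{name}={k}" for k, name in enumerate(lai.ancestries))
    with open(path, "w") as fh:
        fh.write(f"#Subpopulation order/codes: {codes}\n")
        cols = [f"{i}.{j}" for i in range(n) for j in (0, 1)]
        fh.write("#chm\tspos\tepos\tsgpos\tegpos\tn snps\t" + "\t".join(cols) + "\n")
        for w in range(A):
            vals = "\t".join(str(calls[i, j, w]) for i in range(n) for j in (0, 1))
            fh.write(
                f"{chrom}\t{spos[w]}\t{epos[w]}\t{spos[w]/1e6:.5f}\t{epos[w]/1e6:.5f}"
                f"\t1\t{vals}\n"
            )


def write_fb(lai: LocalAncestryField, path: str | Path, chrom: str = "1") -> None:
    """Write per-anchor ancestry probabilities as an RFMix-v2-style fb.tsv."""
    n, _, A, K = lai.probs.shape
    with open(path, "w") as fh:
        fh.write("#reference_panel_population:\t" + "\t".join(lai.ancestries) + "\n")
        heads = [
            f"{i}.{j}:::{anc}"
            for i in range(n)
            for j in (0, 1)
            for anc in lai.ancestries
        ]
        fh.write(
            "chromosome\tphysical_position\tgenetic_position\tgenetic_marker_index\t"
            + "\t".join(heads) + "\n"
        )
        for a in range(A):
            vals = "\t".join(
                f"{lai.probs[i, j, a, k]:.6f}"
                for i in range(n)
                for j in (0, 1)
                for k in range(K)
            )
            fh.write(f"{chrom}\t{lai.anchors[a]}\t{lai.anchors[a]/1e6:.5f}\t{a}\t{vals}\n")


def read_local_ancestry(
    msp_path: str | Path, fb_path: str | Path | None = None
) -> LocalAncestryField:
    """Read RFMix-v2 output into a pointwise ancestry field.

    msp windows are converted to anchor points at their bp midpoints,
    carrying one-hot vectors for the window's hard calls.  If an fb file
    is supplied its probabilities override the one-hot vectors (anchors
    are then the fb marker positions).  Probability rows that miss unit
    sum by more than 0.05 are rejected; smaller discrepancies are
    renormalized with a warning.
    """
    with open(msp_path) as fh:
        code_line = fh.readline()
        if not code_line.startswith("#Subpopulation"):
            raise FormatError("msp file missing '#Subpopulation order/codes' header")
        pairs = code_line.split(":", 1)[1].split()
        by_code: dict[int, str] = {}
        for tok in pairs:
            name, code = tok.rsplit("=", 1)
            by_code[int(code)] = name
        ancestries = [by_code[c] for c in sorted(by_code)]
        if sorted(by_code) != list(range(len(by_code))):
            raise FormatError("msp ancestry codes must be 0..K-1")
        header = fh.readline()
        if not header.startswith("#chm"):
            raise FormatError("msp file missing column header line")
        body = pd.read_csv(fh, sep="\t", header=None)
    K = len(ancestries)
    spos = body.iloc[:, 1].to_numpy(np.int64)
    epos = body.iloc[:, 2].to_numpy(np.int64)
    if np.any(np.diff(spos) < 0):
        raise FormatError("msp windows not sorted")
    if np.any(spos[1:] < epos[:-1]):  # windows may touch but not overlap
        raise FormatError("msp windows overlap")
    calls = body.iloc[:, 6:].to_numpy(np.int64)  # (A, 2n)
    if calls.shape[1] % 2:
        raise FormatError("msp haplotype column count must be 2 x samples")
    if calls.min() < 0 or calls.max() >= K:
        raise FormatError("msp ancestry call outside header codes")
    n = calls.shape[1] // 2
    A = calls.shape[0]
    anchors = (spos + epos) // 2
    probs = np.zeros((n, 2, A, K))
    hap_calls = calls.reshape(A, n, 2).transpose(1, 2, 0)  # (n, 2, A)
    np.put_along_axis(probs, hap_calls[..., None], 1.0, axis=-1)
    if fb_path is not None:
        anchors, probs = _read_fb(fb_path, ancestries, n)
    return LocalAncestryField(ancestries, anchors, probs)


def _read_fb(path: str | Path, ancestries: list[str], n: int):
    with open(path) as fh:
        head = fh.readline()
        if not head.startswith("#reference_panel_population"):
            raise FormatError("fb file missing population header")
        fb_anc = head.split("\t")[1:]
        fb_anc[-1] = fb_anc[-1].strip()
        if fb_anc != list(ancestries):
            raise FormatError("fb ancestry order differs from msp header")
        fh.readline()  # column header
        body = pd.read_csv(fh, sep="\t", header=None)
    K = len(ancestries)
    anchors = body.iloc[:, 1].to_numpy(np.int64)
    vals = body.iloc[:, 4:].to_numpy(np.float64)
    if vals.shape[1] != 2 * n * K:
        raise FormatError("fb probability column count must be 2 x samples x K")
    A = vals.shape[0]
    probs = vals.reshape(A, n, 2, K).transpose(1, 2, 0, 3)
    sums = probs.sum(axis=-1)
    off = np.abs(sums - 1.0)
    if np.any(off > 0.05):
        raise FormatError("fb probability rows deviate from unit sum by > 0.05")
    if np.any(off > 1e-6):
        warnings.warn("fb probabilities renormalized to unit sum")
    probs = probs / sums[..., None]
    return anchors, probs


# ---------------------------------------------------------------------------
# hap-IBD style segment tables, genetic maps


def read_ibd_tsv(path: str | Path) -> IBDSegmentSet:
    """Read a headerless hap-IBD-style TSV (hap codes 1/2)."""
    df = pd.read_csv(path, sep="\t", header=None, names=IBD_COLUMNS,
                     dtype={"sample1": str, "sample2": str, "chrom": str})
    return IBDSegmentSet(df)


def write_ibd_tsv(segs: IBDSegmentSet, path: str | Path) -> None:
    df = segs.df.sort_values(["chrom", "start", "end"]).copy()
    df["length_cm"] = df["length_cm"].map(lambda x: f"{x:.6f}")
    df.to_csv(path, sep="\t", header=False, index=False)


def read_genetic_map(path: str | Path) -> GeneticMap:
    """PLINK-style map: chrom, id, cM, bp (whitespace separated)."""
    df = pd.read_csv(path, sep=r"\s+", header=None,
                     names=["chrom", "id", "cm", "bp"])
    order = np.argsort(df["bp"].to_numpy())
    return GeneticMap(df["bp"].to_numpy()[order], df["cm"].to_numpy()[order])


def write_genetic_map(gmap: GeneticMap, path: str | Path, chrom: str = "1") -> None:
    with open(path, "w") as fh:
        for i, (bp, cm) in enumerate(zip(gmap.bp, gmap.cm)):
            fh.write(f"{chrom}\tpos{i}\t{cm:.8f}\t{int(bp)}\n")


# ---------------------------------------------------------------------------
# frequency VCF


def _fmt_sig(x: float, sig: int = 6) -> str:
    return f"{x:.{sig}g}"


def write_frequency_vcf(
    table: AncestryFrequencyTable,
    chrom: str,
    positions: np.ndarray,
    ref: list[str],
    alt: list[str],
    path: str | Path,
    info_prefix: str = "",
) -> None:
    """Sites-only VCF with AC/AN/AF plus per-ancestry AC_k, AN_k, AF_k, NEFF_k.

    AN_k values are printed with 2 decimals, frequencies with 6
    significant digits; undefined frequencies (AN_k = 0) are ".".
    ``info_prefix`` lets the IBD-corrected table use CORR_* keys.
    """
    for anc in table.ancestries:
        if not anc.replace("_", "").isalnum():
            raise FormatError(f"ancestry name {anc!r} is not a valid INFO key token")
    p = info_prefix
    theta, n_k, af = table.theta, table.n_k, table.af
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        for key, desc in ((f"{p}AC", "ALT allele count"), (f"{p}AN", "Allele number"),
                          (f"{p}AF", "ALT allele frequency")):
            fh.write(f'##INFO=<ID={key},Number=1,Type=Float,Description="{desc}">\n')
        for anc in table.ancestries:
            for stem, desc in (
                ("AC", "weighted ALT count"), ("AN", "weighted allele number"),
                ("AF", "ancestry-specific frequency"), ("NEFF", "effective diploid sample size"),
            ):
                fh.write(
                    f'##INFO=<ID={p}{stem}_{anc},Number=1,Type=Float,'
                    f'Description="{desc}, {anc} ancestry">\n'
                )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        order = np.argsort(positions)
        for m in order:
            parts = [
                f"{p}AC={_fmt_sig(table.ac[m])}",
                f"{p}AN={_fmt_sig(table.an[m])}",
                f"{p}AF={'.' if np.isnan(af[m]) else _fmt_sig(af[m])}",
            ]
            for k, anc in enumerate(table.ancestries):
                parts.append(f"{p}AC_{anc}={table.ac_k[m, k]:.2f}")
                parts.append(f"{p}AN_{anc}={table.an_k[m, k]:.2f}")
                t = theta[m, k]
                parts.append(f"{p}AF_{anc}={'.' if np.isnan(t) else _fmt_sig(t)}")
                parts.append(f"{p}NEFF_{anc}={n_k[m, k]:.2f}")
            fh.write(
                f"{chrom}\t{positions[m]}\t.\t{ref[m]}\t{alt[m]}\t.\t.\t" + ";".join(parts) + "\n"
            )


def read_frequency_vcf(
    path: str | Path, ancestries: list[str], info_prefix: str = ""
) -> tuple[np.ndarray, AncestryFrequencyTable]:
    """Read back a sites-only frequency VCF; returns (positions, table)."""
    p = info_prefix
    vcf = VCF(str(path))
    pos, ac, an, ac_k, an_k = [], [], [], [], []
    for v in vcf:
        pos.append(v.POS)
        ac.append(float(v.INFO[f"{p}AC"]))
        an.append(float(v.INFO[f"{p}AN"]))
        ac_k.append([float(v.INFO[f"{p}AC_{a}"]) for a in ancestries])
        an_k.append([float(v.INFO[f"{p}AN_{a}"]) for a in ancestries])
    vcf.close()
    table = AncestryFrequencyTable(
        list(ancestries), np.array(ac), np.array(an), np.array(ac_k), np.array(an_k)
    )
    return np.array(pos, dtype=np.int64), table
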