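"""One-off generator for the packaged synthetic germline FASTA fixtures.

Writes three files into src/rfpep/data/:
  v_genes_synthetic.fasta        IMGT-gapped amino-acid V genes (heavy/kappa/lambda)
  j_genes_synthetic.fasta        heavy-chain J genes (FR4 anchored at IMGT 128)
  constant_regions_synthetic.fasta   Ig heavy constant regions, 9 accessions /
                                     7 isotype groups, with controlled
                                     shared/unique block structure

The V/J sequences are human-germline-like sequences written from domain
knowledge; the constant regions are seeded-RNG synthetic sequences. All are
stand-ins for reference sets that are not redistributed here, hence the
"_synthetic" suffix.
"""
from __future__ import annotations

import pathlib

import numpy as np

OUT = pathlib.Path(__file__).resolve().parents[1] / "src" / "rfpep" / "data"

# IMGT unique-numbering column widths per region
FR1_W, CDR1_W, FR2_W, CDR2_W, FR3_W = 26, 12, 17, 10, 39


def pad_fr1(seg: str) -> str:
    """Pad FR1 to 26 cols: first 9 residues left-anchored, rest right-anchored."""
    if len(seg) == FR1_W:
        return seg
    n_gap = FR1_W - len(seg)
    return seg[:9] + "." * n_gap + seg[9:]


def pad_fr3(seg: str) -> str:
    """Pad FR3 to 39 cols: first 7 residues left-anchored, rest right-anchored."""
    if len(seg) == FR3_W:
        return seg
    n_gap = FR3_W - len(seg)
    return seg[:7] + "." * n_gap + seg[7:]


def pad_cdr(seg: str, width: int) -> str:
    """IMGT loop gapping: fill from both ends, gaps in the middle."""
    n_gap = width - len(seg)
    left = (len(seg) + 1) // 2
    return seg[:left] + "." * n_gap + seg[left:]


# (name, chain, FR1, CDR1, FR2, CDR2, FR3, CDR3 stub)
V_GENES = [
    ("IGHV3-23*01", "heavy",
     "EVQLLESGGGLVQPGGSLRLSCAAS", "GFTFSSYA", "MSWVRQAPGKGLEWVSA",
     "ISGSGGST", "YYADSVKGRFTISRDNSKNTLYLQMNSLRAEDTAVYYC", "AK"),
    ("IGHV3-23*02", "heavy",
     "EVQLLESGGGLVQPGGSLRLSCAAS", "GFTFSSYA", "MSWVRQAPGKGLEWVSA",
     "ISGSGGST", "YYADSVKGRFTISRDNSKNTLYLQMNSLRAEDTAVYFC", "AK"),
    ("IGHV3-21*01", "heavy",
     "QVQLVESGGGLVKPGGSLRLSCAAS", "GFTFSSYS", "MNWVRQAPGKGLEWVSS",
     "ISSSSSYI", "YYADSVKGRFTISRDNAKNSLYLQMNSLRAEDTAVYYC", "AR"),
    ("IGHV1-69*01", "heavy",
     "QVQLVQSGAEVKKPGSSVKVSCKAS", "GGTFSSYA", "ISWVRQAPGQGLEWMGG",
     "IIPIFGTA", "NYAQKFQGRVTITADESTSTAYMELSSLRSEDTAVYYC", "AR"),
    ("IGHV4-59*01", "heavy",
     "QVQLQESGPGLVKPSETLSLTCTVS", "GGSISSYY", "WSWIRQPPGKGLEWIGY",
     "IYYSGST", "NYNPSLKSRVTISVDTSKNQFSLKLSSVTAADTAVYYC", "AR"),
    ("IGHV4-34*01", "heavy",
     "QVQLQQWGAGLLKPSETLSLTCAVY", "GGSFSGYY", "WSWIRQPPGKGLEWIGE",
     "INHSGST", "NYNPSLKSRVTISVDTSKNQFSLKLSSVTAADTAVYYC", "AR"),
    ("IGKV3-20*01", "kappa",
     "EIVLTQSPGTLSLSPGERATLSCRAS", "QSVSSSY", "LAWYQQKPGQAPRLLIY",
     "GAS", "SRATGIPDRFSGSGSGTDFTLTISRLEPEDFAVYYC", "QQYGSSP"),
    ("IGKV3-11*01", "kappa",
     "EIVLTQSPATLSLSPGERATLSCRAS", "QSVSSY", "LAWYQQKPGQAPRLLIY",
     "DAS", "NRATGIPARFSGSGSGTDFTLTISSLEPEDFAVYYC", "QQRSNW"),
    ("IGKV1-39*01", "kappa",
     "DIQMTQSPSSLSASVGDRVTITCRAS", "QSISSY", "LNWYQQKPGKAPKLLIY",
     "AAS", "SLQSGVPSRFSGSGSGTDFTLTISSLQPEDFATYYC", "QQSYSTP"),
    ("IGKV1-39*02", "kappa",
     "DIQMTQSPSSLSASVGDRVTITCRAS", "QSISSY", "LNWYQQKPGKAPKLLIY",
     "AAS", "SLQSGVPSRFSGSGSGTDFTLTISSLQPEDFATYFC", "QQSYSTP"),
    ("IGKV4-1*01", "kappa",
     "DIVMTQSPDSLAVSLGERATINCKSS", "QSVLYSSNNKNY", "LAWYQQKPGQPPKLLIY",
     "WAS", "TRESGVPDRFSGSGSGTDFTLTISSLQAEDVAVYYC", "QQYYSTP"),
    ("IGLV1-44*01", "lambda",
     "QSVLTQPPSASGTPGQRVTISCSGS", "SSNIGSNT", "VNWYQQLPGTAPKLLIY",
     "SNN", "QRPSGVPDRFSGSKSGTSASLAISGLQSEDEADYYC", "AAWDDSL"),
    ("IGLV1-44*02", "lambda",
     "QSVLTQPPSASGTPGQRVTISCSGS", "SSNIGSNT", "VNWYQQLPGTAPKLLIY",
     "SNN", "QRPSGVPDRFSGSKSGTSASLAISGLQSEDEADYFC", "AAWDDSL"),
    ("IGLV2-14*01", "lambda",
     "QSALTQPASVSGSPGQSITISCTGT", "SSDVGGYNY", "VSWYQQHPGKAPKLMIY",
     "DVS", "NRPSGVSNRFSGSKSGNTASLTISGLQAEDEADYYC", "SSYTSSS"),
    ("IGLV3-21*01", "lambda",
     "SYVLTQPPSVSVAPGQTARITCGGN", "NIGSKS", "VHWYQQKPGQAPVLVVY",
     "DDS", "DRPSGIPERFSGSNSGNTATLTISRVEAGDEADYYC", "QVWDSSS"),
]

J_GENES = [
    ("IGHJ1*01", "heavy", "AEYFQHWGQGTLVTVSS"),
    ("IGHJ2*01", "heavy", "YWYFDLWGRGTLVTVSS"),
    ("IGHJ3*01", "heavy", "DAFDVWGQGTMVTVSS"),
    ("IGHJ4*01", "heavy", "YFDYWGQGTLVTVSS"),
    ("IGHJ5*01", "heavy", "NWFDSWGQGTLVTVSS"),
    ("IGHJ6*01", "heavy", "YYYYYGMDVWGQGTTVTVSS"),
]

AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
# roughly vertebrate-average composition, K/L/F/Y/W present so that the
# Lys-C + chymotrypsin digest yields peptides of useful length
AA_W = np.array([0.07, 0.02, 0.05, 0.06, 0.04, 0.07, 0.02, 0.05, 0.07, 0.09,
                 0.02, 0.04, 0.05, 0.04, 0.05, 0.07, 0.06, 0.06, 0.02, 0.05])
AA_W = AA_W / AA_W.sum()


def rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(AA, size=n, p=AA_W))


def build_constants() -> list[tuple[str, str, str]]:
    rng = np.random.default_rng(20240901)
    shared_g = rand_seq(rng, 60)   # block common to all four IgG subclasses
    shared_a = rand_seq(rng, 50)   # block common to IgA1/IgA2
    recs = []
    for acc, iso in [("P01857", "IgG1"), ("P01859", "IgG2"),
                     ("P01860", "IgG3"), ("P01861", "IgG4")]:
        seq = rand_seq(rng, 130) + shared_g + rand_seq(rng, 130)
        recs.append((acc, iso, seq))
    for acc, iso in [("P01876", "IgA1"), ("P0DOX2", "IgA2")]:
        seq = rand_seq(rng, 130) + shared_a + rand_seq(rng, 130)
        recs.append((acc, iso, seq))
    recs.append(("P01871", "IgM", rand_seq(rng, 340)))

    def near_dup(seq: str) -> str:
        s = list(seq)
        for pos in rng.choice(len(s), size=2, replace=False):
            cur = s[pos]
            s[pos] = rng.choice([a for a in AA if a != cur])
        return "".join(s)

    by_acc = {a: s for a, _, s in recs}
    recs.append(("P0DOX5", "IgG1", near_dup(by_acc["P01857"])))
    recs.append(("P0DOX6", "IgM", near_dup(by_acc["P01871"])))
    return recs


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    with open(OUT / "v_genes_synthetic.fasta", "w") as fh:
        for name, chain, fr1, cdr1, fr2, cdr2, fr3, cdr3 in V_GENES:
            assert len(fr2) == FR2_W, name
            gapped = (pad_fr1(fr1) + pad_cdr(cdr1, CDR1_W) + fr2
                      + pad_cdr(cdr2, CDR2_W) + pad_fr3(fr3) + cdr3)
            fh.write(f">{name}|{chain}|V\n{gapped}\n")
    with open(OUT / "j_genes_synthetic.fasta", "w") as fh:
        for name, chain, seq in J_GENES:
            fh.write(f">{name}|{chain}|J\n{seq}\n")
    with open(OUT / "constant_regions_synthetic.fasta", "w") as fh:
        for acc, iso, seq in build_constants():
            fh.write(f">{acc}|heavy|constant|isotype={iso}\n{seq}\n")
    print("fixtures written to", OUT)


if __name__ == "__main__":
    main()
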