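import random

import pytest

from panelscreen import (
    DiseaseTerm, GenomicRegion, KnownVariant, Panel, RegionOrigin,
    ScoreThresholds, Source, add_disease, load_catalogue, load_kb, new_panel,
)
from panelscreen.panel_model import _Contribution
from panelscreen.knowledgebase import VariantKey

CATALOGUE_TSV = """\
PHENOTYPE\tSOURCE\tGENE\tCHROM\tGENE_START\tGENE_END\tMUT_POS\tMUT_REF\tMUT_ALT
Demo syndrome\tCLINVAR\tGA\t1\t100\t1000\t200\tA\tT
Demo syndrome\tCLINVAR\tGA\t1\t100\t1000\t300\tC\tG
Demo syndrome\tCLINVAR\tGB\t2\t500\t1500\t600\tG\tA
Other disease\tHGMD_PUBLIC\tGB\t2\t500\t1500\t700\tA\tG
Other disease\tHGMD_PUBLIC\tGC\t3\t50\t450\t100\tT\tC
"""

KB_TSV = """\
CHROM\tPOS\tREF\tALT\tGENE\tPHENOTYPE\tSOURCE\tSNP_ID\tSIFT\tPOLYPHEN\tPHASTCONS
1\t200\tA\tT\tGA\tDemo syndrome\tCLINVAR\trs100\t0.01\t0.99\t0.8
1\t200\tA\tT\tGA\tDemo phenotype\tCOSMIC\trs100\t0.01\t0.99\t0.8
1\t300\tC\tG\tGA\tDemo syndrome\tCLINVAR\t.\t.\t0.9\t.
2\t600\tG\tA\tGB\tDemo syndrome\tCLINVAR\t.\t0.2\t.\t0.5
2\t700\tA\tG\tGB\tOther disease\tHGMD_PUBLIC\trs200\t.\t.\t.
3\t100\tT\tC\tGC\tOther disease\tHGMD_PUBLIC\t.\t0.05\t0.5\t0.1
1\t250\tG\tC\tGA\tUnrelated disease\tCLINVAR\t.\t0.9\t0.1\t.
"""

DEMO = DiseaseTerm("Demo syndrome", Source.CLINVAR)
OTHER = DiseaseTerm("Other disease", Source.HGMD_PUBLIC)


@pytest.fixture
def catalogue():
    return load_catalogue(CATALOGUE_TSV)


@pytest.fixture
def kb():
    return load_kb(KB_TSV)


@pytest.fixture
def demo_panel(catalogue):
    panel = new_panel("demo")
    add_disease(panel, DEMO, catalogue)
    add_disease(panel, OTHER, catalogue)
    return panel


def make_vcf(records, contigs=("1", "2", "3"), extra_info=()):
    """Build VCF text from (chrom, pos, id, ref, alt, qual, filter, info) rows."""
    header = ["##fileformat=VCFv4.2"]
    header += [f"##contig=<ID={c},length=100000000>" for c in contigs]
    header += [
        '##INFO=<ID=SIFT,Number=1,Type=Float,Description="s">',
        '##INFO=<ID=POLYPHEN,Number=1,Type=Float,Description="p">',
        '##INFO=<ID=PHASTCONS,Number=1,Type=Float,Description="c">',
        '##INFO=<ID=CSQ,Number=.,Type=String,Description="q">',
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">',
        *extra_info,
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    body = [
        "\t".join(str(f) for f in rec) for rec in records
    ]
    return "\n".join(header + body) + "\n"


def vcf_file(tmp_path, records, name="patient.vcf", **kw):
    path = tmp_path / name
    path.write_text(make_vcf(records, **kw))
    return str(path)


# -- independent normalization oracle ---------------------------------------


def oracle_minimal(pos, ref, alt):
    """Brute-force canonical spelling: among all valid prefix/suffix trims
    (shared bases only, each allele keeps >= 1), pick the shortest total
    allele length, preferring the largest suffix trim on ties.  Written
    independently of the library's iterative trimmer."""
    best = None
    max_i = min(len(ref), len(alt)) - 1
    for i in range(max_i + 1):
        if ref[:i] != alt[:i]:
            break
        for j in range(min(len(ref), len(alt)) - i):
            if ref[len(ref) - j:] != alt[len(alt) - j:]:
                break
            r = ref[i:len(ref) - j] if j else ref[i:]
            a = alt[i:len(alt) - j] if j else alt[i:]
            if not r or not a:
                continue
            cand = (len(r) + len(a), -j, -i)
            if best is None or cand < best[0]:
                best = (cand, (pos + i, r, a))
    assert best is not None
    return best[1]


def random_panel(rng: random.Random) -> Panel:
    """A structurally valid random panel for round-trip testing."""
    panel = new_panel(f"rt-{rng.randrange(10**6)}")
    panel.created = "2026-01-15"
    panel.notes = rng.choice(["", "note", "weird \"quotes\" & <tags>"])
    if rng.random() < 0.5:
        panel.thresholds = ScoreThresholds(
            sift_max=round(rng.random(), 3) if rng.random() < 0.7 else None,
            polyphen_min=round(rng.random(), 3) if rng.random() < 0.7 else None,
        )
    n_regions = rng.randint(0, 6)
    labels = [f"G{k}" for k in range(n_regions)]
    for label in labels:
        start = rng.randint(1, 5000)
        panel.regions.append(GenomicRegion(
            chrom=rng.choice(["1", "2", "X"]),
            start=start, end=start + rng.randint(0, 2000), label=label,
            origin=rng.choice(list(RegionOrigin)),
        ))
    seen = set()
    for _ in range(rng.randint(0, 5)):
        mut = KnownVariant.create(
            chrom=rng.choice(["1", "2"]), pos=rng.randint(1, 9000),
            ref=rng.choice(["A", "C", "AT", "GCA"]),
            alt=rng.choice(["G", "T", "TA"]),
            gene=rng.choice(labels) if labels else "GX",
            phenotype=rng.choice(["P one", "P two"]),
            source=rng.choice(list(Source)),
            snp_id=f"rs{rng.randrange(10**6)}" if rng.random() < 0.5 else None,
            sift=round(rng.random(), 3) if rng.random() < 0.5 else None,
            polyphen=round(rng.random(), 3) if rng.random() < 0.5 else None,
        )
        if mut.key in seen or mut.ref == mut.alt:
            continue
        seen.add(mut.key)
        panel.mutations.append(mut)
    n_terms = rng.randint(0, 2)
    for t in range(n_terms):
        term = DiseaseTerm(f"Disease {t}", rng.choice(list(Source)))
        panel.diseases.append(term)
        contributed_keys = {
            m.key for m in panel.mutations if rng.random() < 0.5
        }
        panel.contributions[term] = _Contribution(
            region_labels={l for l in labels if rng.random() < 0.5},
            mutation_keys=contributed_keys,
        )
    return panel
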