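from __future__ import annotations

import textwrap

import pytest

from poolassoc import PoolSpec, SiteCounts


def make_site(i, depth_case, alt_case, depth_ctrl, alt_ctrl) -> SiteCounts:
    return SiteCounts(
        site_id=f"s{i:02d}",
        chrom="chr4",
        pos=100 * i,
        ref="A",
        alt="G",
        depth_case=depth_case,
        alt_case=alt_case,
        depth_ctrl=depth_ctrl,
        alt_ctrl=alt_ctrl,
    )


def make_ranking_table() -> list[SiteCounts]:
    """Twenty sites with heterogeneous depths, built so that the top-3
    priorities under the naive and the full (k=3) variance models differ.

    Sites 1-3 have large frequency differences at very low depth (40 reads):
    the naive model, blind to depth, ranks them first, while the full model
    demotes them.  Sites 4-6 have moderate differences at depth 6000 and
    take over the top ranks under the full model.  The rest are near-null
    fillers at depth 2000.
    """
    sites = [
        make_site(1, 40, 30, 40, 10),
        make_site(2, 40, 29, 40, 10),
        make_site(3, 40, 29, 40, 11),
        make_site(4, 6000, 3840, 6000, 2160),
        make_site(5, 6000, 3810, 6000, 2190),
        make_site(6, 6000, 3780, 6000, 2220),
    ]
    for i in range(7, 21):
        alt_case = 600 + 5 * (i - 7)
        sites.append(make_site(i, 2000, alt_case, 2000, 590))
    return sites


@pytest.fixture
def ranking_sites() -> list[SiteCounts]:
    return make_ranking_table()


@pytest.fixture
def pool320() -> PoolSpec:
    return PoolSpec(n_individuals=320)


VCF_TEXT = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr4,length=100000000>
    ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
    ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tCASE\tCTRL
    chr4\t100\trs1\tA\tG\t.\tPASS\t.\tDP:AD\t1000:700,300\t900:720,180
    chr4\t200\t.\tAC\tA\t.\tPASS\t.\tDP:AD\t500:400,100\t600:540,60
    chr4\t300\trs3\tT\tC\t.\tPASS\t.\tDP:AD\t800:80,720\t750:600,150
    chr4\t400\t.\tG\tA,T\t.\tPASS\t.\tDP:AD\t200:100,50,50\t200:120,40,40
    chr4\t500\t.\tC\tT\t.\tPASS\t.\tDP\t300\t280
    """
)


@pytest.fixture
def vcf_path(tmp_path):
    path = tmp_path / "pools.vcf"
    path.write_text(VCF_TEXT)
    return path


TSV_TEXT = textwrap.dedent(
    """\
    chrom\tpos\tref\talt\tcase_depth\tcase_alt\tctrl_depth\tctrl_alt
    chr4\t100\tA\tG\t1000\t300\t900\t180
    chr4\t200\tAC\tA\t500\t100\t600\t60
    chr4\t300\tT\tC\t800\t720\t750\t150
    chr4\t400\tG\tA\t2000\t900\t2000\t950
    chr4\t500\tC\tT\t1500\t30\t1600\t40
    """
)


@pytest.fixture
def tsv_path(tmp_path):
    path = tmp_path / "counts.tsv"
    path.write_text(TSV_TEXT)
    return path
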