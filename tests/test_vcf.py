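import numpy as np
import pytest

from hap_panel import transcripts as tx
from hap_panel.variants import (VcfError, normalize_variant, read_vcf,
                                report_table, read_report_table,
                                write_report_table)
from tests._oracles import normalize_oracle

HEADER = """##fileformat=VCFv4.2
##contig=<ID=panel_ref,length={n}>
##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="GQ">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def _write(tmp_path, body, samples=("S1", "S2")):
    ref = tx.reference_sequence()
    path = tmp_path / "t.vcf"
    path.write_text(
        HEADER.format(n=len(ref), samples="\t".join(samples)) + body)
    return path


def _pos_in(panel, gene, reference):
    region = panel.regions_for(gene)[3]
    pos = (region.start + region.end) // 2
    return pos + 1, reference[pos]  # 1-based, ref base


def test_one_site_two_carriers_gives_two_records(panel, reference, tmp_path):
    pos, ref = _pos_in(panel, "BMPR2", reference)
    alt = "A" if ref != "A" else "G"
    body = (f"panel_ref\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\t"
            f"GT:GQ:DP\t0/1:99:100\t1/1:80:90\n")
    records = read_vcf(_write(tmp_path, body), panel)
    assert len(records) == 2
    zyg = {r.sample_id: r.zygosity for r in records}
    assert zyg == {"S1": "het", "S2": "hom"}
    assert all(r.gene == "BMPR2" and not r.off_target for r in records)
    assert records[0].quality == 99 and records[0].depth == 100


def test_multiallelic_site_is_decomposed(panel, reference, tmp_path):
    pos, ref = _pos_in(panel, "TBX4", reference)
    alts = [b for b in "ACGT" if b != ref][:2]
    body = (f"panel_ref\t{pos}\t.\t{ref}\t{','.join(alts)}\t.\tPASS\t.\t"
            f"GT:GQ:DP\t0/1:99:100\t0/2:99:100\n")
    records = read_vcf(_write(tmp_path, body), panel)
    assert len(records) == 2
    assert {r.alt for r in records} == set(alts)
    assert all(r.zygosity == "het" for r in records)


def test_reference_mismatch_names_the_site(panel, reference, tmp_path):
    pos, ref = _pos_in(panel, "ENG", reference)
    wrong = "A" if ref != "A" else "C"
    body = (f"panel_ref\t{pos}\t.\t{wrong}\tT\t.\tPASS\t.\t"
            f"GT:GQ:DP\t0/1:99:100\t0/0:99:100\n")
    with pytest.raises(VcfError, match=str(pos)):
        read_vcf(_write(tmp_path, body), panel)


def test_missing_gt_format_is_an_error(panel, tmp_path):
    ref = tx.reference_sequence()
    path = tmp_path / "nogt.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        f"##contig=<ID=panel_ref,length={len(ref)}>\n"
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
    )
    with pytest.raises(VcfError, match="GT"):
        read_vcf(path, panel)


def test_off_target_record_is_flagged(panel, reference, tmp_path):
    pos = 10  # inside the leading flank, before any target
    ref = reference[pos - 1]
    alt = "A" if ref != "A" else "G"
    body = (f"panel_ref\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\t"
            f"GT:GQ:DP\t0/1:99:100\t0/0:99:100\n")
    (rec,) = read_vcf(_write(tmp_path, body), panel)
    assert rec.off_target and rec.gene is None


def test_equivalent_indel_representations_normalize_identically(
        panel, reference, tmp_path):
    """A deletion in a homopolymer written two ways maps to one key."""
    # build a run: find 'XYYY...' inside a target to delete one Y from
    region = panel.regions_for("NOTCH3")[2]
    seg_start = region.start + 30
    run_pos = None
    for i in range(seg_start, region.end - 40):
        if reference[i] == reference[i + 1]:
            run_pos = i
            break
    assert run_pos is not None
    base = reference[run_pos]
    # two VCF spellings of deleting one base of the run
    p1 = run_pos          # 1-based anchor just before the run
    body = (
        f"panel_ref\t{p1}\t.\t{reference[p1 - 1]}{base}\t{reference[p1 - 1]}\t.\tPASS\t.\t"
        f"GT:GQ:DP\t0/1:99:100\t0/0:99:100\n"
        f"panel_ref\t{p1 + 1}\t.\t{base}{reference[run_pos + 1]}\t{base}\t.\tPASS\t.\t"
        f"GT:GQ:DP\t0/0:99:100\t0/1:99:100\n"
    )
    records = read_vcf(_write(tmp_path, body), panel)
    assert len(records) == 2
    assert records[0].key == records[1].key


def test_left_alignment_matches_exhaustive_oracle():
    rng = np.random.default_rng(1234)
    bases = np.array(list("ACGT"))
    for _ in range(200):
        seq = "".join(rng.choice(bases, size=60))
        pos = int(rng.integers(20, 40))
        if rng.random() < 0.5:  # deletion
            dlen = int(rng.integers(1, 4))
            ref = seq[pos - 1:pos + dlen]
            alt = seq[pos - 1]
        else:  # insertion
            ins = "".join(rng.choice(bases, size=int(rng.integers(1, 4))))
            ref = seq[pos - 1]
            alt = ref + ins
        got = normalize_variant("c", pos, ref, alt, seq)
        assert got == normalize_oracle(pos, ref, alt, seq)


def test_report_table_round_trip(fixture_run, tmp_path):
    records = fixture_run["candidates"]
    out = tmp_path / "report.tsv"
    df = write_report_table(records, out)
    again = read_report_table(out)
    assert list(again.columns) == list(df.columns)
    assert len(again) == len(records)
    assert list(again["Patient ID"]) == list(df["Patient ID"])
    assert list(again["Variant"]) == list(df["Variant"])


def test_empty_report_is_header_only(tmp_path):
    out = tmp_path / "empty.tsv"
    write_report_table([], out)
    assert out.read_text().strip() == "\t".join(
        ["Patient ID", "PAH Etiology", "Variant", "GT", "ACMG Classification"])
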