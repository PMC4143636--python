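import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from ngla.pedigree import PedigreeError
from ngla.simulate import SimConfig, simulate_study
from ngla.study_io import (
    MarkerPanel,
    StudyFormatError,
    read_study,
    write_results,
    write_study,
)

MINI_PED = "1\tf\t0\t0\t1\t0\n1\tm\t0\t0\t2\t0\n1\tc\tf\tm\t1\t0\n"
MINI_MAP = "3\trs1\t10.0\t1000\n3\trs2\t20.0\t2000\n"
MINI_VCF = """##fileformat=VCFv4.2
##contig=<ID=3>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tf\tm\tc
3\t1000\trs1\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0\t0/1
3\t2000\trs2\tC\tT\t.\tPASS\t.\tGT\t1/1\t0/1\t./.
"""
MINI_PHENO = "id\tsbp\ttreated\tage\nf\t121.5\t0\t61\nm\t\t1\t60\nc\t\t0\t30\n"


def _write_mini(tmp_path: Path, vcf=MINI_VCF, ped=MINI_PED):
    files = {"study.ped": ped, "study.map": MINI_MAP, "study.vcf": vcf,
             "pheno.tsv": MINI_PHENO}
    for name, content in files.items():
        (tmp_path / name).write_text(content)
    return (tmp_path / "study.ped", tmp_path / "study.map",
            tmp_path / "study.vcf", tmp_path / "pheno.tsv")


def test_minimal_trio_study_reads_correctly(tmp_path):
    bundle = read_study(*_write_mini(tmp_path))
    assert len(bundle.pedigrees) == 1 and len(bundle.pedigrees[0]) == 3
    assert len(bundle.panel) == 2
    assert bundle.genotypes.column(0) == {"f": 1, "m": 0, "c": 1}
    assert bundle.genotypes.column(1) == {"f": 2, "m": 1, "c": -1}
    assert bundle.phenotypes.loc["f", "sbp"] == 121.5
    assert bool(bundle.phenotypes.loc["m", "treated"]) is True
    assert np.isnan(bundle.phenotypes.loc["c", "sbp"])


def test_unknown_vcf_sample_warned_and_dropped(tmp_path):
    vcf = MINI_VCF.replace("\tf\tm\tc", "\tf\tm\tc\tzz").replace(
        "GT\t0/1\t0/0\t0/1", "GT\t0/1\t0/0\t0/1\t0/0").replace(
        "GT\t1/1\t0/1\t./.", "GT\t1/1\t0/1\t./.\t0/0")
    with pytest.warns(UserWarning, match="zz"):
        bundle = read_study(*_write_mini(tmp_path, vcf=vcf))
    assert "zz" not in bundle.genotypes.ids


def test_single_parent_ped_row_errors(tmp_path):
    ped = MINI_PED.replace("1\tc\tf\tm", "1\tc\tf\t0")
    with pytest.raises(PedigreeError, match="one parent"):
        read_study(*_write_mini(tmp_path, ped=ped))


def test_non_diallelic_site_errors_in_strict_mode(tmp_path):
    vcf = MINI_VCF.replace("3\t1000\trs1\tA\tG", "3\t1000\trs1\tA\tG,T").replace(
        "GT\t0/1\t0/0\t0/1", "GT\t0/1\t0/0\t0/2")
    paths = _write_mini(tmp_path, vcf=vcf)
    with pytest.raises(StudyFormatError, match="diallelic"):
        read_study(*paths)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundle = read_study(*paths, strict=False)
    assert len(bundle.panel) == 1  # offending site skipped


def test_duplicated_marker_ids_rejected():
    tab = pd.DataFrame({
        "marker": ["a", "a"], "chrom": "3", "cm": [1.0, 2.0],
        "bp": [10, 20], "ref": ["A", "C"], "alt": ["G", "T"]})
    with pytest.raises(StudyFormatError, match="duplicated"):
        MarkerPanel(tab)


def test_unsorted_positions_rejected_not_reordered():
    tab = pd.DataFrame({
        "marker": ["a", "b"], "chrom": "3", "cm": [5.0, 2.0],
        "bp": [10, 20], "ref": ["A", "C"], "alt": ["G", "T"]})
    with pytest.raises(StudyFormatError, match="sorted"):
        MarkerPanel(tab)


def test_round_trip_preserves_everything(tmp_path):
    bundle, _ = simulate_study(SimConfig(
        n_families=2, family_size_range=(6, 10), n_markers=18, seed=3))
    paths = write_study(bundle, tmp_path / "rt")
    again = read_study(paths["ped"], paths["map"], paths["vcf"],
                       paths["pheno"], paths["annot"])
    assert again.genotypes.ids == bundle.genotypes.ids
    assert (again.genotypes.dosage == bundle.genotypes.dosage).all()
    assert list(again.panel.table["ref"]) == list(bundle.panel.table["ref"])
    assert list(again.panel.table["alt"]) == list(bundle.panel.table["alt"])
    assert np.array_equal(again.panel.cm, bundle.panel.cm)
    ph = again.phenotypes.loc[bundle.phenotypes.index]
    assert np.allclose(ph["sbp"], bundle.phenotypes["sbp"], equal_nan=True)
    assert (ph["treated"].to_numpy() == bundle.phenotypes["treated"].to_numpy()).all()


def test_ped_genotype_dialect_fallback(tmp_path):
    ped_geno = ("1\tf\t0\t0\t1\t0\tA G\tC C\n"
                "1\tm\t0\t0\t2\t0\tA A\tC T\n"
                "1\tc\tf\tm\t1\t0\tA G\t0 0\n").replace(" ", "\t")
    p = tmp_path / "geno.ped"
    p.write_text(ped_geno)
    (tmp_path / "study.ped").write_text(MINI_PED)
    (tmp_path / "study.map").write_text(MINI_MAP)
    (tmp_path / "pheno.tsv").write_text(MINI_PHENO)
    bundle = read_study(tmp_path / "study.ped", tmp_path / "study.map", p,
                        tmp_path / "pheno.tsv")
    assert bundle.genotypes.column(0) == {"f": 1, "m": 0, "c": 1}
    assert bundle.genotypes.column(1)["c"] == -1


def test_write_results_deterministic_and_collision_safe(tmp_path):
    df = pd.DataFrame({"pos_cM": [1.0, 2.0], "BF": [1.5, 0.7], "PPL": [0.03, 0.014]})
    paths = write_results({"ppl": df}, tmp_path, seed=7, cfg_hash="abc")
    body1 = paths["ppl"].read_text()
    with pytest.raises(FileExistsError):
        write_results({"ppl": df}, tmp_path, seed=7, cfg_hash="abc")
    paths2 = write_results({"ppl": df}, tmp_path, seed=7, cfg_hash="abc", overwrite=True)
    assert paths2["ppl"].read_text() == body1
    assert body1.startswith("# seed=7 config_hash=abc")
    assert "pos_cM\tBF\tPPL" in body1


def test_empty_table_writes_header_only(tmp_path):
    df = pd.DataFrame(columns=["variant", "PPLD"])
    paths = write_results({"ppld": df}, tmp_path, seed=1)
    lines = paths["ppld"].read_text().strip().splitlines()
    assert lines[1] == "variant\tPPLD" and len(lines) == 2
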