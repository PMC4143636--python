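"""Study containers and on-disk formats.

This module is the single home for coordinate and allele conventions:

* Genetic map positions are cM (float); physical positions are 1-based bp
  as in VCF.  Both are carried on every marker.
* Genotypes are dosages of the ALT allele (0/1/2, -1 missing).  The
  "minor" allele used by filters is computed from founders only; REF/ALT
  labels are preserved for reporting.
* Missing genotype is "./." in VCF and "0 0" in PED; missing phenotype is
  an empty field.  Internally: dosage -1 and NaN.

Formats: LINKAGE/PLINK-style PED (6 fixed columns, optional allele
columns as a fallback genotype dialect), MAP (chrom, id, cM, bp), VCF v4.2
diallelic SNVs (genotype source of record), phenotype TSV
(id, sbp, treated, age) and annotation TSV (chrom, pos, ref, alt,
phastcons44).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .pedigree import Individual, Pedigree, PedigreeError
from .trait import standardize_phenotypes

__all__ = [
    "MarkerPanel",
    "GenotypeMatrix",
    "StudyBundle",
    "StudyFormatError",
    "read_study",
    "write_study",
    "write_results",
]

MISSING_DOSAGE = -1


class StudyFormatError(ValueError):
    """Malformed or inconsistent study input."""


def _fmt_float(x: float) -> str:
    return "" if x is None or (isinstance(x, float) and np.isnan(x)) else repr(float(x))


@dataclass
class MarkerPanel:
    """Ordered diallelic markers with genetic (cM) and physical (bp) positions.

    ``table`` columns: marker, chrom, cm, bp, ref, alt.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        req = ["marker", "chrom", "cm", "bp", "ref", "alt"]
        missing = [c for c in req if c not in self.table.columns]
        if missing:
            raise StudyFormatError(f"marker panel missing columns {missing}")
        t = self.table
        if t["marker"].duplicated().any():
            dup = t.loc[t["marker"].duplicated(), "marker"].iloc[0]
            raise StudyFormatError(f"duplicated marker ID {dup!r}")
        for chrom, grp in t.groupby("chrom", sort=False):
            if not grp["cm"].is_monotonic_increasing:
                raise StudyFormatError(
                    f"cM positions not sorted within chromosome {chrom}; "
                    "genomic tables must be sorted, not silently reordered"
                )
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> list[str]:
        return self.table["marker"].tolist()

    @property
    def cm(self) -> np.ndarray:
        return self.table["cm"].to_numpy(float)

    @property
    def bp(self) -> np.ndarray:
        return self.table["bp"].to_numpy(np.int64)

    def index_of(self, marker: str) -> int:
        hits = np.nonzero((self.table["marker"] == marker).to_numpy())[0]
        if hits.size == 0:
            raise KeyError(marker)
        return int(hits[0])


@dataclass
class GenotypeMatrix:
    """ALT-allele dosages, individuals x markers; -1 is missing."""

    ids: list[str]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int16)
        if self.dosage.ndim != 2 or self.dosage.shape[0] != len(self.ids):
            raise StudyFormatError("genotype matrix shape does not match sample IDs")
        self._row = {s: i for i, s in enumerate(self.ids)}

    def row(self, iid: str) -> int:
        return self._row[iid]

    def column(self, j: int, ids: list[str] | None = None) -> dict[str, int]:
        """Dosage dict for marker j, restricted to ``ids`` (default: all)."""
        sel = self.ids if ids is None else ids
        return {s: int(self.dosage[self._row[s], j]) for s in sel if s in self._row}


@dataclass
class StudyBundle:
    """All inputs of one family study, validated and cross-indexed."""

    pedigrees: list[Pedigree]
    phenotypes: pd.DataFrame  # index iid; columns sbp, treated, age
    panel: MarkerPanel
    genotypes: GenotypeMatrix
    annotations: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "pos", "ref", "alt", "phastcons44"]))

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        fam_of: dict[str, str] = {}
        for ped in self.pedigrees:
            for iid in ped.ids:
                if iid in fam_of:
                    raise StudyFormatError(
                        f"individual {iid} appears in families {fam_of[iid]} and {ped.family_id}"
                    )
                fam_of[iid] = ped.family_id
        for iid in self.genotypes.ids:
            if iid not in fam_of:
                raise StudyFormatError(f"genotyped individual {iid} not in any pedigree")
        for iid in self.phenotypes.index:
            if iid not in fam_of:
                raise StudyFormatError(f"phenotyped individual {iid} not in any pedigree")
        if self.genotypes.dosage.shape[1] != len(self.panel):
            raise StudyFormatError("genotype matrix does not match marker panel size")
        sbp = self.phenotypes["sbp"]
        bad = sbp[(~sbp.isna()) & ((~np.isfinite(sbp)) | (sbp <= 0))]
        if len(bad):
            raise StudyFormatError(f"non-finite or non-positive SBP for {bad.index[0]}")
        ann = self.annotations
        if len(ann):
            for chrom, grp in ann.groupby("chrom", sort=False):
                if not grp["pos"].is_monotonic_increasing:
                    raise StudyFormatError(
                        f"annotation table not sorted by position on chromosome {chrom}"
                    )
        self._fam_of = fam_of

    # -- cross-indexing helpers ------------------------------------------
    def family_of(self, iid: str) -> str:
        return self._fam_of[iid]

    def pedigree(self, family_id: str) -> Pedigree:
        for p in self.pedigrees:
            if p.family_id == family_id:
                return p
        raise KeyError(family_id)

    def founder_ids(self, family_id: str | None = None) -> list[str]:
        peds = self.pedigrees if family_id is None else [self.pedigree(family_id)]
        return [m.iid for p in peds for m in p.founders]

    def alt_freq(self, j: int | None = None, family_id: str | None = None,
                 founders_only: bool = True) -> np.ndarray | float:
        """ALT-allele frequency from observed genotypes (founders only by default)."""
        ids = self.founder_ids(family_id) if founders_only else (
            self.genotypes.ids if family_id is None
            else [i for i in self.genotypes.ids if self._fam_of[i] == family_id])
        rows = [self.genotypes.row(i) for i in ids if i in self.genotypes._row]
        D = self.genotypes.dosage[rows]
        if j is not None:
            D = D[:, [j]]
        obs = D >= 0
        with np.errstate(invalid="ignore"):
            freq = np.where(obs.sum(axis=0) > 0,
                            (D * obs).sum(axis=0) / (2.0 * np.maximum(obs.sum(axis=0), 1)),
                            np.nan)
        return float(freq[0]) if j is not None else freq

    def minor_dosage(self, j: int, family_id: str | None = None) -> dict[str, int]:
        """Minor-allele dosages for marker j (minor derived from founders)."""
        f = self.alt_freq(j, family_id=family_id)
        col = self.genotypes.column(j)
        if not np.isnan(f) and f > 0.5:
            return {i: (2 - d if d >= 0 else -1) for i, d in col.items()}
        return col

    def pheno_obs(self, family_id: str | None = None, standardize: bool = True):
        """Phenotype observations for the likelihood engines.

        Returns (obs dict iid -> None|'treated'|float, center, scale).
        Standardization uses the untreated observed SBP of the whole study.
        """
        ph = self.phenotypes
        if standardize:
            _, center, scale = standardize_phenotypes(ph["sbp"].to_numpy(float))
        else:
            center, scale = 0.0, 1.0
        ids = (ph.index if family_id is None
               else [i for i in ph.index if self._fam_of[i] == family_id])
        obs: dict[str, object] = {}
        for iid in ids:
            row = ph.loc[iid]
            if bool(row["treated"]):
                obs[iid] = "treated"
            elif np.isfinite(row["sbp"]):
                obs[iid] = (float(row["sbp"]) - center) / scale
            else:
                obs[iid] = None
        return obs, center, scale


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_ped(path: Path) -> tuple[list[Pedigree], list[list[str]] | None, list[str]]:
    """Parse a PED file -> (pedigrees, optional allele columns, sample order)."""
    fams: dict[str, list[Individual]] = {}
    alleles: list[list[str]] = []
    order: list[str] = []
    have_geno = None
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        tok = line.split()
        if len(tok) < 6:
            raise StudyFormatError(f"{path}:{ln}: PED rows need 6 fixed columns")
        fam, iid, fa, mo, sex = tok[0], tok[1], tok[2], tok[3], tok[4]
        if (fa == "0") != (mo == "0"):
            raise PedigreeError(
                f"{path}:{ln}: individual {iid} has exactly one parent specified"
            )
        fams.setdefault(fam, []).append(
            Individual(iid, None if fa == "0" else fa, None if mo == "0" else mo,
                       int(sex) if sex in "012" else 0, fam)
        )
        order.append(iid)
        g = tok[6:]
        if have_geno is None:
            have_geno = bool(g)
        if bool(g) != have_geno or (have_geno and len(g) % 2):
            raise StudyFormatError(f"{path}:{ln}: inconsistent PED genotype columns")
        alleles.append(g)
    peds = [Pedigree(fam, members) for fam, members in fams.items()]
    return peds, (alleles if have_geno else None), order


def _read_map(path: Path) -> pd.DataFrame:
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        tok = line.split()
        if len(tok) < 4:
            raise StudyFormatError(f"{path}:{ln}: MAP rows are chrom, id, cM, bp")
        rows.append((tok[0], tok[1], float(tok[2]), int(tok[3])))
    return pd.DataFrame(rows, columns=["chrom", "marker", "cm", "bp"])


def _read_vcf(path: Path, strict: bool = True):
    """Read diallelic SNV records -> (marker table rows, sample list, dosage array)."""
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    rows, cols = [], []
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            if strict:
                raise StudyFormatError(
                    f"{path}: non-diallelic site {rec.chrom}:{rec.pos} in strict mode"
                )
            warnings.warn(f"skipping non-diallelic site {rec.chrom}:{rec.pos}")
            continue
        rows.append((rec.id or f"{rec.chrom}_{rec.pos}", rec.chrom, rec.pos,
                     rec.ref, rec.alts[0]))
        dos = np.full(len(samples), MISSING_DOSAGE, dtype=np.int16)
        for k, s in enumerate(samples):
            gt = rec.samples[s].get("GT")
            if gt is not None and None not in gt:
                dos[k] = sum(1 for a in gt if a == 1)
        cols.append(dos)
    vf.close()
    return rows, samples, (np.stack(cols, axis=1) if cols else
                           np.zeros((len(samples), 0), dtype=np.int16))


def read_study(ped_path, map_path, geno_path, pheno_path, annot_path=None,
               strict: bool = True) -> StudyBundle:
    """Read and cross-validate a full study.

    ``geno_path`` may be a VCF (source of record) or a PED with allele
    columns (fallback dialect; alleles matched against the MAP order).
    Genotyped samples absent from the pedigrees are reported and dropped.
    """
    peds, _, _ = _read_ped(Path(ped_path))
    known = {i for p in peds for i in p.ids}
    mp = _read_map(Path(map_path))

    geno_path = Path(geno_path)
    if geno_path.suffix in (".vcf", ".gz", ".bcf"):
        vrows, samples, dosage = _read_vcf(geno_path, strict=strict)
        vtab = pd.DataFrame(vrows, columns=["marker", "chrom", "bp", "ref", "alt"])
        if len(vtab) != len(mp):
            mp = mp[mp["marker"].isin(vtab["marker"])].reset_index(drop=True)
        panel_tab = mp.merge(vtab[["marker", "ref", "alt"]], on="marker", how="inner")
    else:
        gpeds, alleles, order = _read_ped(geno_path)
        if alleles is None:
            raise StudyFormatError(f"{geno_path}: PED genotype dialect needs allele columns")
        samples = order
        m = len(mp)
        dosage = np.full((len(order), m), MISSING_DOSAGE, dtype=np.int16)
        refalt: list[tuple[str, str]] = [("1", "2")] * m
        allele_sets: list[dict[str, int]] = [dict() for _ in range(m)]
        for r, g in enumerate(alleles):
            if len(g) != 2 * m:
                raise StudyFormatError(f"{geno_path}: row {order[r]} has {len(g)//2} genotypes, map has {m}")
            for j in range(m):
                a1, a2 = g[2 * j], g[2 * j + 1]
                if a1 == "0" or a2 == "0":
                    continue
                for a in (a1, a2):
                    allele_sets[j].setdefault(a, len(allele_sets[j]))
                if max(allele_sets[j].values()) > 1:
                    raise StudyFormatError(f"{geno_path}: marker {mp['marker'][j]} not diallelic")
                dosage[r, j] = (allele_sets[j][a1] + allele_sets[j][a2])
        refalt = [(sorted(s, key=s.get)[0] if s else "1",
                   sorted(s, key=s.get)[1] if len(s) > 1 else "2") for s in allele_sets]
        panel_tab = mp.copy()
        panel_tab["ref"] = [ra[0] for ra in refalt]
        panel_tab["alt"] = [ra[1] for ra in refalt]

    drop = [s for s in samples if s not in known]
    if drop:
        warnings.warn(f"dropping {len(drop)} genotyped sample(s) not in any pedigree: {drop[:5]}")
        keep = [k for k, s in enumerate(samples) if s in known]
        samples = [samples[k] for k in keep]
        dosage = dosage[keep]

    pheno = pd.read_csv(pheno_path, sep="\t", dtype={"id": str})
    pheno = pheno.set_index("id")
    pheno["sbp"] = pd.to_numeric(pheno["sbp"], errors="coerce")
    pheno["treated"] = pheno["treated"].astype(int).astype(bool)
    pheno["age"] = pd.to_numeric(pheno["age"], errors="coerce")
    pheno = pheno.loc[[i for i in pheno.index if i in known]]

    if annot_path is not None:
        ann = pd.read_csv(annot_path, sep="\t", dtype={"chrom": str})
    else:
        ann = pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "phastcons44"])

    panel_tab = panel_tab[["marker", "chrom", "cm", "bp", "ref", "alt"]]
    return StudyBundle(
        pedigrees=peds,
        phenotypes=pheno,
        panel=MarkerPanel(panel_tab),
        genotypes=GenotypeMatrix(samples, dosage),
        annotations=ann,
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_study(bundle: StudyBundle, out_dir) -> dict[str, Path]:
    """Write a StudyBundle to out_dir in the canonical formats.

    Produces study.ped, study.map, study.vcf, phenotypes.tsv,
    annotations.tsv.  write_study followed by read_study round-trips the
    bundle exactly (allele labels, missingness pattern included).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    ped_lines = []
    for ped in bundle.pedigrees:
        for m in ped.members:
            ped_lines.append(
                f"{ped.family_id}\t{m.iid}\t{m.father or 0}\t{m.mother or 0}\t{m.sex}\t0"
            )
    paths["ped"] = out / "study.ped"
    paths["ped"].write_text("\n".join(ped_lines) + "\n")

    t = bundle.panel.table
    map_lines = [f"{r.chrom}\t{r.marker}\t{_fmt_float(r.cm)}\t{r.bp}" for r in t.itertuples()]
    paths["map"] = out / "study.map"
    paths["map"].write_text("\n".join(map_lines) + "\n")

    vcf = ["##fileformat=VCFv4.2",
           '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    for chrom in t["chrom"].astype(str).unique():
        vcf.append(f"##contig=<ID={chrom}>")
    vcf.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
               + "\t".join(bundle.genotypes.ids))
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING_DOSAGE: "./."}
    D = bundle.genotypes.dosage
    for j, r in enumerate(t.itertuples()):
        gts = "\t".join(gt_str[int(D[i, j])] for i in range(D.shape[0]))
        vcf.append(f"{r.chrom}\t{r.bp}\t{r.marker}\t{r.ref}\t{r.alt}\t.\tPASS\t.\tGT\t{gts}")
    paths["vcf"] = out / "study.vcf"
    paths["vcf"].write_text("\n".join(vcf) + "\n")

    ph = bundle.phenotypes
    lines = ["id\tsbp\ttreated\tage"]
    for iid, row in ph.iterrows():
        lines.append(
            f"{iid}\t{_fmt_float(row['sbp'])}\t{int(bool(row['treated']))}\t{_fmt_float(row['age'])}"
        )
    paths["pheno"] = out / "phenotypes.tsv"
    paths["pheno"].write_text("\n".join(lines) + "\n")

    ann = bundle.annotations
    lines = ["chrom\tpos\tref\talt\tphastcons44"]
    for r in ann.itertuples():
        lines.append(f"{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\t{_fmt_float(r.phastcons44)}")
    paths["annot"] = out / "annotations.tsv"
    paths["annot"].write_text("\n".join(lines) + "\n")
    return paths


def config_hash(obj) -> str:
    """Stable short hash of a configuration object for run metadata."""
    import json

    def default(o):
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dict__"):
            return vars(o)
        return str(o)

    blob = json.dumps(obj, default=default, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_results(tables: dict[str, pd.DataFrame], out_dir, *, seed: int,
                  cfg_hash: str = "", overwrite: bool = False) -> dict[str, Path]:
    """Write result tables as TSV with a run-metadata header.

    Column order is taken from each DataFrame; re-running with the same
    seed and configuration produces byte-identical files.
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    header = f"# seed={seed} config_hash={cfg_hash} version={__version__}\n"
    for name, df in tables.items():
        p = out / f"{name}.tsv"
        if p.exists() and not overwrite:
            raise FileExistsError(f"{p} exists; pass overwrite=True to replace it")
        body = df.to_csv(sep="\t", index=False, float_format="%.10g")
        p.write_text(header + body)
        paths[name] = p
    return paths
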