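# Template for a run on real downloaded data (requires files on disk;
# nothing in this package downloads them).  The discovery cohort of the
# original NASH study is GEO series GSE61260 (Affymetrix HuGene 1.1 ST,
# platform GPL11532; NASH n=24, healthy-obese n=24, NAFL n=23); the
# validation series are GSE33814 (Illumina HumanWG-6 v3, GPL6884) and
# GSE14323 (HG-U133A).  Alterations/survival: cBioPortal TCGA liver
# cohort exports (353 patients).
#
# Expected formats:
#   matrix:       TSV, first column `gene`, one column per sample
#                 (collapse probe-level series matrices first with
#                 litsig's reader + platform map)
#   groups:       TSV `sample<TAB>group`
#   corpus:       TSV `gene<TAB>term<TAB>count` with `#total_docs=` line
#   interactions: two-column interactor TSV (InnateDB export)
#   alterations:  TSV `patient<TAB>gene<TAB>alteration_class`
#   survival:     TSV `patient<TAB>time_months<TAB>event`
out_dir: litsig_run_geo
seed: 1
synthetic: null
paths:
  corpus: data/cooccurrence_lipid_terms.tsv
  matrix: data/GSE61260_collapsed.tsv
  groups: data/GSE61260_groups.tsv
  interactions: data/innatedb_partners.tsv
  alterations: data/tcga_lihc_alterations.tsv
  survival: data/tcga_lihc_survival.tsv
  # annotation: data/go_bp.gmt      # optional, enables the enrich stage
group_pair: [HO, NASH]
hub: YWHAZ
stages: [mine, reduce, sam, pca, markers, prioritize, partners, survival]
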