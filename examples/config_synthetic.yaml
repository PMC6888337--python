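# Fully-worked configuration: end-to-end run on the synthetic bundle.
# Every input is generated with planted ground truth; run with
#   litsig run --config examples/config_synthetic.yaml
out_dir: litsig_run
seed: 1
synthetic: {}        # empty dict = generator defaults (500 genes, 87
                     # literature-associated, 25 DE, 24/24/23 samples,
                     # 353-patient alteration cohort with a 5-gene core)
q_text: 0.05         # BH q cutoff for literature gene selection
fdr_sam: 0.05        # SAM permutation-FDR target
q_axis: 0.05         # BH q cutoff for PCA axis contributors
alt_threshold: 0.04  # alteration-frequency core-gene cutoff
sam_permutations: 500
prioritize_k: 10
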