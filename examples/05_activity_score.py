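"""The composite activity-element score, term by term.

score_AE = sum(Peak_En x length_En)/L + sum(Peak_CA x length_CA)/L
         + sum(Score_TF x count_TF)/L for an SE of length L. Enhancer and
accessibility terms are signal times effective (in-SE) length; the TFBS
term is each TF's enrichment score times its site count.
"""
from seforge import ActivityElement, GenomicInterval, compute_activity_score
from seforge.activity import score_terms

element = ActivityElement(
    se_interval=GenomicInterval("chr1", 0, 2_000),
    enhancers=[(4.0, 1_000)],        # signal 4 covering 1000 bp of the SE
    accessibility=[(6.0, 500)],      # ATAC signal 6 covering 500 bp
    tfbs_groups=[(2.0, 3)],          # one TF, enrichment 2.0, 3 sites
)
t_en, t_ca, t_tf = score_terms(element)
score = compute_activity_score(element)
print(f"enhancer term      {t_en:.4f}   (4 x 1000 / 2000)")
print(f"accessibility term {t_ca:.4f}   (6 x 500 / 2000)")
print(f"TFBS term          {t_tf:.4f}   (2.0 x 3 / 2000)")
print(f"score_AE           {score:.4f}")
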