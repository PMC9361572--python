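"""Divergence times from Ks via the molecular clock T = Ks / 2r.

Uses the lineage-aware rate selector: within Apiaceae the neutral rate
is 5.2e-9 substitutions/site/year, while celery vs. Arabidopsis uses
the general dicot rate 1.5e-8.
"""

from ksdater import divergence_time, select_rate
from ksdater.synthetic_families import ORTHOLOG_KS_EXTREMES

for (sp_a, sp_b), ks in ORTHOLOG_KS_EXTREMES.items():
    rate = select_rate(sp_a, sp_b)
    t = divergence_time(ks, rate, pair_id=f"{sp_a}-{sp_b}")
    print(
        f"{sp_a:>7} vs {sp_b:<12} Ks = {ks:.4f}  "
        f"r = {rate.r:.1e} ({rate.name})  T = {t.T:6.2f} Mya"
    )

print()
print(
    "These Ks values are the smallest among each ortholog set, so the\n"
    "printed times are the lower ends of the divergence-time ranges:\n"
    "the most recently diverged celery-coriander orthologs split ~10.6 Mya,\n"
    "the youngest celery-Arabidopsis orthologs ~44.7 Mya."
)
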