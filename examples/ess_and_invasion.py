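"""Which mechanism wins: the analytical game at one parameter point.

Computes the ESS target helper proportion for fully random and fully
coordinated specialization in a clonal group of ten cells, then asks
which mechanism can invade the other at its resident equilibrium.
"""

from labordiv import (
    ModelParams,
    classify_region,
    ess_coordinated_closed,
    ess_random_closed,
)

params = ModelParams(l=1, m=10, epsilon=1.0, theta=0.025)

q_fr = ess_random_closed(params)
q_fc = ess_coordinated_closed(params)
report = classify_region(params)

print(f"group: l={params.l} lineages x m={params.m} cells, "
      f"essentiality eps={params.epsilon}, coordination cost theta={params.theta}")
print(f"ESS helper target, random specializers     q_FR* = {q_fr.q_star:.4f}")
print(f"ESS helper target, coordinated specializers q_FC* = {q_fc.q_star:.4f}")
print(f"random invades coordinated: {report.random_invades_coordinated}")
print(f"coordinated invades random: {report.coordinated_invades_random}")
print(f"outcome: {report.region.value}")

# Both mechanisms sustain half the group as sterile helpers, but in a
# small clonal group with essential cooperation the precision of
# coordination outweighs its cost: coordinated specialization invades
# random specialization and not vice versa.
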