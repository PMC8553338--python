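"""Reject the 'bound Regnase-1 is still active' model.

The observation to explain: at late stimulation times, free Regnase-1
AND its target mRNAs are all comparable between wild-type and S513A
cells.  Imposing the matched free-protein level on both genotypes, each
model predicts the mRNA fixed points; Model 1 (bound protein inactive)
predicts exact equality, Model 2 (bound protein active) forces WT mRNA
strictly below S513A — contradicting the observation.
"""

from reg1dyn import (
    Genotype,
    ModelKind,
    discriminate,
    equilibrium_closed_form,
    solve_k2_for_target_x3,
)
from reg1dyn.defaults import default_parameters

s_input, matched_x3 = 1.0, 0.4

for kind in ModelKind:
    params = default_parameters(kind)
    v = discriminate(params, s_input, matched_x3)
    print(f"{kind.value}: Il6 WT {v.X1_WT:.4f} vs S513A {v.X1_SA:.4f} "
          f"({v.relation_x1.value}); Zc3h12a WT {v.X2_WT:.4f} vs "
          f"S513A {v.X2_SA:.4f} ({v.relation_x2.value})")
    print(f"  consistent with 'no mRNA difference': "
          f"{v.consistent_with_no_difference}")

# The same verdict from full equilibria: engineer a WT parameter set whose
# free-protein fixed point equals the S513A one by inverting the
# equilibrium quadratic for k2, then compare the complete closed forms.
params2 = default_parameters(ModelKind.MODEL_2)
eq_sa = equilibrium_closed_form(params2, Genotype.S513A, s_input)
k2_matched = solve_k2_for_target_x3(params2, Genotype.WT, s_input, eq_sa.X3)
eq_wt = equilibrium_closed_form(params2.replace(k2=k2_matched), Genotype.WT, s_input)
print(f"\nEnd-to-end (Model 2): matching X3 = {eq_sa.X3:.4f} needs "
      f"k2 = {k2_matched:.4f}; the full equilibria then give Il6 "
      f"WT {eq_wt.X1:.4f} < S513A {eq_sa.X1:.4f} — the same strict "
      "inequality, so the shortcut is faithful to the full model.")
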