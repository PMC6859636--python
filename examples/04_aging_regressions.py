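"""Evaluate the published seed-aging regressions of each trait.

The regressions predict a trait value from the number of days a maize seed
spent under artificial aging (45 C, 90% humidity); traits decline with
aging, which is what makes root phenotypes a proxy for seed vigor.
"""

from rootpcj import regress_trait

print("aging day ->  RTN    RTL(mm)  RTW(mm)  REL(cm)")
for day in (0, 2, 4, 7):
    print(f"   {day:2d}      {regress_trait(day, 'RTN'):6.2f}"
          f"  {regress_trait(day, 'RTL'):7.1f}"
          f"  {regress_trait(day, 'RTW'):7.2f}"
          f"  {regress_trait(day, 'REL'):7.2f}")
print("(the polynomials are descriptive fits; outside the sampled aging"
      " range they extrapolate poorly, as any cubic does)")
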