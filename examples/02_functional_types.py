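"""Derive model parameters from bee trait profiles.

Every functional type is a distinct combination of five traits; all of its
dynamic parameters (growth rate r, competition factor c, land-use
suitabilities, dispersal kernel, disturbance susceptibility) are exact table
lookups on those traits.  Prints the derivation for two contrasting types
and the default 28-type community roster.
"""

from bitz import TraitProfile, default_community, derive_parameters
from bitz.functional_types import Diet, FlyingPeriod, ForagingDistance, Nesting

for profile in (
    TraitProfile(ForagingDistance.SHORT, Diet.OLIGOLECTIC, FlyingPeriod.FIRST,
                 Nesting.ENDOGEIC, parasite_host=False),
    TraitProfile(ForagingDistance.LONG, Diet.POLYLECTIC, FlyingPeriod.BOTH,
                 Nesting.HYPOGEAN, parasite_host=True),
):
    p = derive_parameters(profile)
    print(f"{p.ft_id}:")
    print(f"  r = {p.r}  c = {p.c}  dispersal {p.disp_mean:.0f} +- {p.disp_sd:.0f} m  "
          f"dist_eff = {p.dist_eff}")
    print(f"  forage suitability (bare/arable/forest/grass/urban/water): {p.forage_suitability}")
    print(f"  nest   suitability                                       : {p.nest_suitability}")

community = default_community(28, seed=1)
print(f"\ndefault roster: {community.size} distinct functional types, e.g.")
for ft_id in community.ft_ids()[:5]:
    print(f"  {ft_id}")
print("  ...")
# a low c is a strong competitor; only types with overlapping flying periods compete
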