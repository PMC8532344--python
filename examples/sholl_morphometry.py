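"""Sholl analysis and morphometry of a synthetic Purkinje-cell tree.

Generates a branching SWC morphology (180-um apical trunk with lateral
branches and spine annotations on the distal 10 um), then measures the
Sholl profile (intersections with concentric 5-um spheres), the
soma-to-most-apical-point length, and the spine density.
"""

from pcsense import morphology, synthgen

params = synthgen.TreeParams(apical_extent=180.0, branch_prob=0.35,
                             spine_density=2.3)
tree, spines = synthgen.gen_morphology(params, seed=11)

profile = morphology.sholl(tree, step=5.0)
peak = profile.radii_um[profile.intersections.argmax()]
print(f"{tree.n_nodes} nodes; Sholl over {profile.radii_um.size} radii, "
      f"max {profile.intersections.max()} intersections at {peak:.0f} um")
print("profile:", {int(r): int(c) for r, c in
                   zip(profile.radii_um[:8], profile.intersections[:8])}, "...")
print(f"apical length {morphology.apical_length(tree):.1f} um "
      f"(generator extent {params.apical_extent:.0f} um)")
print(f"spine density {morphology.spine_density(spines):.2f} spines/um "
      f"({len(spines)} spines on 10 um)")

# The apical length equals the generator's extent because the trunk is the
# longest path; the Sholl profile exceeds 1 wherever lateral branches cross
# the same spheres as the trunk.
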