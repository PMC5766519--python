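"""Interaction persistence: the mechanistic signature panel.

Plants the E380-H377 side-chain hydrogen bond at 85% occupancy in monomer A
and runs the built-in signature panel (3.3 A / 35 deg H-bond rule).  The
planted row recovers the occupancy; signatures whose atoms do not exist in
this topology (e.g. the serine-537 bond in a wild-type receptor, or ligand
salt bridges in an apo system) are reported as not applicable.
"""

from erassay import HBondPlant, SyntheticSpec, generate_trajectory, signature_panel

spec = SyntheticSpec(
    seed=5,
    n_frames=800,
    sigma=0.5,
    hbond_plants=(
        HBondPlant(
            label="E380-H377",
            donor=("A", 377, "NE2"),
            hydrogen=("A", 377, "HE2"),
            acceptor=("A", 380, "OE1"),
            occupancy=0.85,
        ),
    ),
)
top, traj, truth = generate_trajectory(spec)
panel = signature_panel(top, traj, isoform="WT", ligand="END")

cols = ["chain", "label", "kind", "persistence_pct", "applicable"]
print(panel[cols].to_string(index=False))
print()
planted = 100 * truth.hbond_formed["E380-H377"].mean()
print(f"planted occupancy: {planted:.1f}%  (panel row above should match)")
print("The E380-H377 bond stabilises the antagonist H12 pose; its loss is")
print("read as a signature of (partial) receptor activation.")
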