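# spiderstat

Static force modelling for cage-and-elastic-cord rehabilitation devices
(SPIDER-type verticalization cages).

In these devices, elastic cords (expanders) run from anchor points on a
metal cage to a belt at the patient's waist. Depending on whether a cord
is anchored above or below the waist it partially *unweights* (supports)
or deliberately *loads* the patient, which therapists use to train
balance, verticalization and symmetric weight-bearing after stroke,
cerebral palsy and other neurological conditions. Historically the cord
settings were chosen by feel; `spiderstat` turns them into numbers: it
tells the therapist what forces a given configuration applies to the
body and what configuration achieves a prescribed support level.

## The model

Each cord type's tension is a three-term sum of sines of the elongation
*x* (percent of rest length, 0–100 %):

    T(x) = a₁·sin(b₁x + c₁) + a₂·sin(b₂x + c₂) + a₃·sin(b₃x + c₃)   [N]

fitted to bench dynamometer data by seeded multi-start nonlinear least
squares (tension is floored at 0 N — cords cannot push). All belt-routed
cord forces are reduced to two kinds of points: the body's centre of
gravity (COG) and the two foot–ground contacts (FGC). With cord unit
directions **dᵢ** (belt → anchor) and tensions Tᵢ:

* COG resultant: **F** = Σ Tᵢ **dᵢ**; the *unweighting fraction* is
  u = F_z / (m·g), positive when the cords carry weight, negative when
  they add load.
* Foot reactions: vertical components solve force balance plus the
  lateral moment balance about the COG's floor projection (a 2×2 linear
  system); the net horizontal cord force is reacted at the feet in
  proportion to vertical load. Positive cord-imposed Z at a foot
  unweights the heel, negative loads it; the Y component moves load
  toward or away from the toe mound.
* Inverse planning: the forward map u(elongation) is monotone on a
  cord's working range (20–80 % elongation), so a prescribed u is solved
  by Brent root-finding and verified by forward simulation.

The frame is anatomical: Z up, X anterior, Y toward the subject's left;
origin on the floor between the feet.

Because no absolute cord force tables are published for the physical
device, the package ships two *synthetic, calibrated* reference
characteristics (`reference_adult_thick`, `reference_child_thin`),
fitted to smooth saturating bench curves anchored so that the two
standard worked configurations reproduce their known support levels
(15 % of body weight for a 75 kg adult with four thick cords at 45°
and 250 mm stretch; 16 % for a 12 kg child with four thin cords at 10°
and 100 mm). They are labelled as constructions, not measurements.

## Worked example

Simulate the packaged 75 kg adult scenario (four thick cords, 45°
COG-level angle, 250 mm elongation each):

```sh
spiderstat simulate \
    --scenario src/spiderstat/data/scenarios/adult_symmetric_unweight.yaml \
    --out forces.csv
```

prints

```
Subject: 75 kg, COG height 0.980 m
Cords: 4
Body unweighted by 15.0% of body weight
COG resultant [N]: x=-0.00 y=-0.00 z=+110.45
Left foot  [N]: x=+0.00 y=+0.00 z=+312.65  heel=unweighted toe=neutral
Right foot [N]: x=+0.00 y=+0.00 z=+312.65  heel=unweighted toe=neutral
```

Each cord pulls 39.05 N at 40.5 % elongation; the four vertical
components sum to 110.45 N = 15.0 % of the 735.75 N body weight, and the
remaining 625.3 N splits evenly between the feet (312.65 N each) because
the configuration is symmetric. `forces.csv` holds the per-cord and
per-point force components.

The inverse problem — what elongation gives 10 % support with the same
geometry:

```sh
spiderstat plan \
    --scenario src/spiderstat/data/scenarios/adult_symmetric_unweight.yaml \
    --target-unweight 0.10
# solved elongation: 26.7253%
# achieved unweighting: 0.100000
```

Other subcommands: `spiderstat synth` writes a synthetic bench CSV;
`spiderstat fit` fits a characteristic JSON from bench data
(`elongation_pct,force_N` columns).

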