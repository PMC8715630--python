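# Metric registry

Session feature names, units, and the evaluation task each derives from.
Session values are the arithmetic mean of per-segment values over
non-degenerate segments.

## Shoulder-elbow robot (planar endpoint, metres)

Point-to-point reaching (8 targets on a 14 cm circle):

| name | unit | meaning |
|---|---|---|
| `aim` | rad | unsigned angle between the velocity at the first speed peak and the straight line to the target |
| `duration` | s | movement attempt duration |
| `deviation` | m | RMS perpendicular distance from the start-to-target chord |
| `dwell_time` | s | terminal time inside the target radius below 5% of peak speed |
| `mean_speed` | m/s | path length / duration |
| `peak_speed` | m/s | maximum tangential speed |
| `speed_shape` | – | mean/peak speed ratio, in (0, 1]; 8/15 for a minimum-jerk reach |
| `jerk_discrete` | – | dimensionless squared jerk, ∫j² dt · D⁵/A² (720 for minimum jerk) |
| `jerk_rhythmic` | – | mean-speed-normalized squared jerk, ∫j² dt · D/v̄² |
| `sub_number` | – | submovements per movement |
| `sub_duration` | s | mean submovement support duration |
| `sub_overlap` | s | mean onset-to-previous-offset overlap of consecutive submovements |
| `sub_peak` | m/s | mean submovement peak speed |
| `sub_interpeak` | s | mean interval between consecutive submovement peaks |

Circle drawing (CW/CCW × two starts):
`circle_major`, `circle_minor` (m, best-fit ellipse semi-axes),
`circle_axis_ratio` (minor/major), `circle_orientation` (rad),
`circle_joint_independence` (Pearson r of IK shoulder vs elbow angles),
`horizontal_axes` (m, horizontal extent of the drawn conditions).

Movement against resistance: `max_displacement` (m), `overall_aim` (rad,
circular mean of signed per-attempt aims).

Isometric stabilization: `scatter` (m, RMS about the held mean), `offset`
(m, mean displacement from the commanded hold point).

Kinetic (force transducer): `shoulder_f`, `shoulder_e`, `shoulder_ab`,
`shoulder_ad` (N, per-direction mean peak force over 5 trials each) and
`deltaz` (N, mean of the four direction means).

## Wrist/forearm robot (angles, radians)

The same macro and submovement metrics with a `wrist_` prefix for the
8-target pointing task on the 60°×30° ellipse, and a `forearm_` prefix for
the ±30° pronation/supination task (`forearm_deviation` is identically 0 in
the 1-D task and carried for layout symmetry).  Force-loaded wrist tasks
give `wrist_max_displacement`, `wrist_overall_aim`, `wrist_scatter`,
`wrist_offset` (rad).
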