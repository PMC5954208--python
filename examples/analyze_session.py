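"""Segment a walking session into bouts and summarize its path variety.

Generates one synthetic 20-min free-play session, splits it into walking
bouts (a >= 0.5 s stationary gap ends a bout), and prints the four variety
dimensions: SE of per-bout curvature (shape), SE of step-to-step heading
change (direction), SE of steps per bout (length), and the bout count.
"""

from varietywalk import PathGenParams, generate_session, segment_bouts, variety_profile

session = generate_session(PathGenParams(seed=3), "demo-walker")
bouts = segment_bouts(session)
profile = variety_profile(session)

print(f"session {session.session_id}: {session.n_steps} steps, {len(bouts)} bouts")
print(f"median steps/bout: {sorted(b.n_steps for b in bouts)[len(bouts) // 2]}")
print(f"shape variety     (SE of path curvature): {profile.shape_variety:.4f}")
print(f"direction variety (SE of heading change): {profile.direction_variety:.3f} deg")
print(f"length variety    (SE of steps per bout): {profile.length_variety:.3f} steps")
print(f"starts and stops  (number of bouts):      {profile.n_bouts}")
print()
print("Higher values mean more varied walking: a wider spread of path")
print("shapes, step directions, and bout lengths within this one walker.")
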