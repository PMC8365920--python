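"""Walk with the shipped reflex controller and report the episode score.

The reflex baseline runs a stance/swing finite-state machine per leg with
force feedback on the stance extensors and length-feedback swing flexion.
The shipped parameter file was tuned by this repository's own evolution
strategy (see tune_reflex_gait.py); it demonstrates sustained alternating
stepping, not human-like gait.
"""

import planargait as pg
from planargait.control import (ReflexState, reflex_policy,
                                shipped_reflex_params)

env = pg.PlanarWalkEnv(pg.EpisodeConfig(seed=2, mode="planar-18",
                                        max_steps=1500))
obs = env.reset()
params = shipped_reflex_params()
state = pg.ReflexState()
done = False
while not done:
    action, state = reflex_policy(obs, params, state, mode="planar-18")
    obs, reward, done, info = env.step(action)

result = info["result"]
touchdowns = [f for f in result.footsteps if f.duration < 5.0]
print(pg.report_text(result))
print(f"distance walked: {env.state.q[0]:.2f} m in "
      f"{info['step'] * 0.01:.1f} s; footstep events: {len(touchdowns)}")
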