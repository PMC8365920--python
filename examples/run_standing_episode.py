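"""Run the physics environment with the standing baseline controller.

The stand policy co-activates the knee/hip muscles and balances with an
ankle strategy (plantarflexors against forward sway). Standing earns the
alive bonus every step plus forced-closure footstep rewards reduced by the
velocity cost of not moving toward the target, and the effort cost of the
muscle activity holding the pose.
"""

import planargait as pg

env = pg.PlanarWalkEnv(pg.EpisodeConfig(seed=1, mode="compat-22",
                                        max_steps=500))
obs = env.reset()
done = False
while not done:
    obs, reward, done, info = env.step(pg.stand_policy(obs))

result = info["result"]
print(pg.report_text(result))
print(f"final pelvis height: {env.state.pelvis_height:.3f} m "
      f"(fall threshold {env.config.fall_threshold} m)")
print("R_alive = 0.1/step for staying up; the negative footstep rewards"
      "\nreflect the velocity cost of standing still while the field"
      "\ncommands 1.4 m/s toward the target.")
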