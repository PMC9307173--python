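"""Conditioned-place-preference (CPP) scores from pre/post test times.

The CPP score is the time spent on the drug-paired side in the 900-s
post-conditioning test minus the time in the 900-s pre-conditioning test;
positive scores indicate a rewarding (addiction-related) effect.
"""

from oxsleep import cpp_score

sessions = [
    ("rewarding agonist", 310.0, 545.0),
    ("neutral agonist", 420.0, 435.0),
    ("aversive treatment", 480.0, 360.0),
]

for label, pre, post in sessions:
    r = cpp_score(pre, post)
    print(f"{label:<20} pre {r.pre_s:5.0f} s   post {r.post_s:5.0f} s   CPP score {r.score_s:+6.0f} s")
print()
print("A score near zero means no place preference developed; a clearly")
print("positive score is the behavioural marker of a reinforcing drug.")
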