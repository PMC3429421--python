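"""The exact trinomial test for insertion-supported branches.

Under a hard-polytomy null each independent marker supports one of the
three resolutions of a local trichotomy with probability 1/3.  With k
unopposed markers the p-value is (1/3)^k: one marker proves nothing,
three reach p < 0.05, five reach p < 0.01.
"""

from sinephylo import sine_likelihood_test, stars_for

print(" k  m  n     p-value  stars")
for k, m, n in [(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0), (5, 0, 0),
                (6, 0, 0), (10, 0, 0), (19, 0, 0), (6, 1, 1), (4, 3, 3)]:
    p = sine_likelihood_test(k, m, n)
    star = {"none": "", "one": "*", "two": "**"}[stars_for(p)]
    print(f"{k:2d} {m:2d} {n:2d}  {p:10.3e}  {star}")

print("\nwith conflicting markers (m, n > 0) the same support count is "
      "less convincing; the test is symmetric in the two alternatives")
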