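# SYNTHETIC risk-of-bias flags.  The source evidence base notes that three of
# the twelve trials had evidence of masking (blinding) bias without naming
# them; this file is a constructed stand-in that marks three open-label trials
# as not low-risk so the sensitivity restriction exercises a 9-trial network.
trial_id,low_risk
weber2015,0
ribas2015,1
larkin2015,1
postow2015,1
robert2015a,1
robert2015b,1
hodi2014,1
ribas2013,0
robert2011,1
hodi2010,1
hersh2011,0
weber2009,1
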