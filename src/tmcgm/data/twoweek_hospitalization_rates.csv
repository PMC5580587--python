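year,DD,HD,CD
2006,2.3,12.2,2.7
2007,3,11.4,6.7
2008,3.3,10.2,3.6
2009,7.6,11.9,5.1
2010,8.2,13.5,6.9
2011,9.3,14.7,7.5
2012,10.7,16.1,8.9
2013,11.4,17.5,10.7
2014,10.5,18.3,11.6
2015,12.5,19.9,12.3
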