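compound,parent,green_algae,daphnid,mysid,fish
MINP,,1.929,7.553,1.288,5.131
MEHP,,4.05,14.669,3.115,9.454
MINP-C6H5,MINP,53.691,149.574,66.591,80.731
MEHP-F,MEHP,9.966,33.081,8.984,20.10
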