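site,location,bird,n_minfreq,n_amplitude
Rural,Commonweal,Male 1,1,1
Rural,Commonweal,Male 2,4,4
Rural,Commonweal,Male 3,2,1
Rural,Commonweal,Male 4,2,2
Rural,Commonweal,Male 5,5,2
Rural,Abbott's Lagoon,Male 6,3,1
Rural,Abbott's Lagoon,Male 7,4,1
Rural,Abbott's Lagoon,Male 8,16,8
Rural,Abbott's Lagoon,Male 9,5,2
Rural,Abbott's Lagoon,Male 10,7,3
Rural,Abbott's Lagoon,Male 11,3,1
Urban,Baker's Beach,Male 12,4,1
Urban,Land's End,Male 13,3,1
Urban,Land's End,Male 14,3,1
Urban,Land's End,Male 15,3,1
Urban,Land's End,Male 16,7,1
Urban,Land's End,Male 17,5,1
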